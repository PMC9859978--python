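"""Apply seeded random leaf mutations to a model store.

Input payload: ``{"seed": "<int>", "count": "<k>"}``. Samples *k* distinct
scalar leaves and perturbs each (deterministically for a given seed), then
writes the store back. Used to exercise detection of multi-field changes.

Usage: ``python -m plansnap.examples.apply_mutations <store> <input.json>``
"""

import json
import random
import sys

from plansnap.model import (
    apply_mutation,
    load_model,
    sample_set_value_mutations,
    store_model,
)


def main(argv=None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 2:
        print(__doc__, file=sys.stderr)
        return 2
    store, input_file = argv
    with open(input_file, encoding="utf-8") as fh:
        payload = json.load(fh)
    rng = random.Random(int(payload.get("seed", 0)))
    k = int(payload.get("count", 1))
    model = load_model(store)
    for spec in sample_set_value_mutations(model, k, rng):
        model = apply_mutation(model, spec)
    store_model(model, store)
    return 0


if __name__ == "__main__":
    sys.exit(main())
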