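"""A script-under-test that changes nothing (exit 0, store untouched).

Usage: ``python -m plansnap.examples.noop <store> <input.json>``
"""

import sys


def main(argv=None) -> int:
    return 0


if __name__ == "__main__":
    sys.exit(main())
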