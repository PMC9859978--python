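"""Rename a course and its plan to standard nomenclature.

Emulates a plan-labeling script: renames the given course and plan, appends
a save-history entry and an ApplicationScriptLog to the plan. The timestamp
comes from the input payload (fixed default) so runs are reproducible.

Usage: ``python -m plansnap.examples.rename_course_and_plan <store> <input.json>``
"""

import json
import sys

from plansnap.model import ApplicationScriptLog, HistoryEntry, load_model, resolve, store_model

SCRIPT_NAME = "RenameCourseAndPlan"
DEFAULT_TIMESTAMP = "2022-06-01T09:00:00Z"


def main(argv=None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 2:
        print(__doc__, file=sys.stderr)
        return 2
    store, input_file = argv
    with open(input_file, encoding="utf-8") as fh:
        payload = json.load(fh)
    model = load_model(store)
    course = resolve(model, f"course[{payload['course_id']}]")
    plan = resolve(model, f"course[{payload['course_id']}]/plan[{payload['plan_id']}]")
    course.id = payload["new_course_id"]
    plan.id = payload["new_plan_id"]
    ts = payload.get("timestamp", DEFAULT_TIMESTAMP)
    user = payload.get("user", "script")
    plan.history.append(
        HistoryEntry(timestamp=ts, user=user, action=f"Ids updated by {SCRIPT_NAME}")
    )
    plan.script_logs.append(
        ApplicationScriptLog(script_name=SCRIPT_NAME, timestamp=ts, user=user)
    )
    store_model(model, store)
    return 0


if __name__ == "__main__":
    sys.exit(main())
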