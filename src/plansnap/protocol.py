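"""Declarative test protocols.

A protocol is the tester's complete description of an automated run: which
model stores to use, which subjects to snapshot, which script to execute
with what input, and how to compare. It lives in a plain-text block format
so that a run can be repeated verbatim, and an equivalent JSON form and a
programmatic builder (:func:`build_protocol`) exist for generated regimes.

Text grammar (one directive per line, ``#`` comments, blank lines ignored)::

    [options]
    output_dir = out
    timeout = 300
    rename_threshold = 0.5
    detect_renames = true
    tolerance.<leaf field> = <abs value>
    ignore = <path glob>            # repeatable

    [case] <case id>
    store = <model store directory>
    subject = <kind> <path> [-> <post-run path>]
    script = <command, shlex-quoted; {store} {input} {python} placeholders>
    input.<key> = <value>
    gold = <subject path> <snapshot xml file>

Unknown directives are rejected with their line number.
"""

from __future__ import annotations

import json
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from .diff import CompareOptions
from .errors import ProtocolError

DEFAULT_TIMEOUT = 300.0


@dataclass
class Subject:
    kind: str  # patient_summary | plan_detailed | structure_set_detailed
    path: str
    post_path: Optional[str] = None  # expected path after a renaming script


@dataclass
class TestCase:
    case_id: str
    store_dir: str
    subjects: List[Subject] = field(default_factory=list)
    script_command: List[str] = field(default_factory=list)
    input_payload: Dict[str, str] = field(default_factory=dict)
    gold_standard_refs: Dict[str, str] = field(default_factory=dict)


@dataclass
class TestProtocol:
    cases: List[TestCase] = field(default_factory=list)
    options: CompareOptions = field(default_factory=CompareOptions)
    output_dir: str = "plansnap_out"
    timeout: float = DEFAULT_TIMEOUT


def _validate(protocol: TestProtocol) -> TestProtocol:
    seen = set()
    for case in protocol.cases:
        if not case.case_id:
            raise ProtocolError("case with empty id")
        if case.case_id in seen:
            raise ProtocolError(f"duplicate case id {case.case_id!r}")
        seen.add(case.case_id)
        if not case.subjects:
            raise ProtocolError(f"case {case.case_id!r}: no subjects")
        if not case.store_dir:
            raise ProtocolError(f"case {case.case_id!r}: no store")
        if not case.script_command and not case.gold_standard_refs:
            raise ProtocolError(
                f"case {case.case_id!r}: no script and no gold standard (nothing to test)"
            )
    return protocol


def build_protocol(
    cases: List[TestCase],
    options: Optional[CompareOptions] = None,
    output_dir: str = "plansnap_out",
    timeout: float = DEFAULT_TIMEOUT,
) -> TestProtocol:
    """Programmatic protocol construction; equivalent to the text file —
    saving a built protocol and reloading it yields an equal protocol."""
    return _validate(
        TestProtocol(
            cases=list(cases),
            options=options or CompareOptions(),
            output_dir=output_dir,
            timeout=timeout,
        )
    )


# ---------------------------------------------------------------------------
# Text format

def save_protocol(protocol: TestProtocol, path) -> None:
    lines: List[str] = ["[options]"]
    lines.append(f"output_dir = {protocol.output_dir}")
    lines.append(f"timeout = {protocol.timeout!r}")
    lines.append(f"rename_threshold = {protocol.options.rename_similarity_threshold!r}")
    lines.append(f"detect_renames = {'true' if protocol.options.detect_renames else 'false'}")
    for k in sorted(protocol.options.numeric_tolerance):
        lines.append(f"tolerance.{k} = {protocol.options.numeric_tolerance[k]!r}")
    for pat in protocol.options.ignore_paths:
        lines.append(f"ignore = {pat}")
    for case in protocol.cases:
        lines.append("")
        lines.append(f"[case] {case.case_id}")
        lines.append(f"store = {case.store_dir}")
        for s in case.subjects:
            arrow = f" -> {s.post_path}" if s.post_path else ""
            lines.append(f"subject = {s.kind} {s.path}{arrow}")
        if case.script_command:
            lines.append(f"script = {shlex.join(case.script_command)}")
        for k in sorted(case.input_payload):
            lines.append(f"input.{k} = {case.input_payload[k]}")
        for sp in sorted(case.gold_standard_refs):
            lines.append(f"gold = {sp} {case.gold_standard_refs[sp]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_protocol(path) -> TestProtocol:
    """Load a protocol from the text format (or JSON, by content sniffing)."""
    p = Path(path)
    try:
        text = p.read_text(encoding="utf-8")
    except OSError as e:
        raise ProtocolError(f"cannot read protocol {p}: {e}") from e
    if text.lstrip().startswith("{"):
        return _from_json(text, p)
    return _from_text(text, p)


def _from_text(text: str, path: Path) -> TestProtocol:
    protocol = TestProtocol()
    case: Optional[TestCase] = None
    in_options = False
    saw_section = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue

        def err(msg: str) -> ProtocolError:
            return ProtocolError(f"{path}:{lineno}: {msg}")

        if line == "[options]":
            in_options, case, saw_section = True, None, True
            continue
        if line.startswith("[case]"):
            cid = line[len("[case]"):].strip()
            if not cid:
                raise err("missing case id after [case]")
            case = TestCase(case_id=cid, store_dir="")
            protocol.cases.append(case)
            in_options, saw_section = False, True
            continue
        if "=" not in line:
            raise err(f"expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if in_options:
            _parse_option(protocol, key, value, err)
        elif case is not None:
            _parse_case_line(case, key, value, err)
        else:
            raise err("directive before any [options] or [case] section")
    if not saw_section:
        raise ProtocolError(f"{path}: empty protocol file (no sections)")
    try:
        return _validate(protocol)
    except ProtocolError as e:
        raise ProtocolError(f"{path}: {e}") from e


def _parse_option(protocol: TestProtocol, key: str, value: str, err) -> None:
    try:
        if key == "output_dir":
            protocol.output_dir = value
        elif key == "timeout":
            protocol.timeout = float(value)
        elif key == "rename_threshold":
            protocol.options.rename_similarity_threshold = float(value)
        elif key == "detect_renames":
            protocol.options.detect_renames = value.lower() == "true"
        elif key.startswith("tolerance."):
            protocol.options.numeric_tolerance[key[len("tolerance."):]] = float(value)
        elif key == "ignore":
            protocol.options.ignore_paths.append(value)
        else:
            raise err(f"unknown option {key!r}")
    except ValueError as e:
        raise err(str(e)) from e


def _parse_case_line(case: TestCase, key: str, value: str, err) -> None:
    if key == "store":
        case.store_dir = value
    elif key == "subject":
        post = None
        if "->" in value:
            value, _, post = value.partition("->")
            post = post.strip()
        parts = value.split()
        if len(parts) != 2:
            raise err(f"subject needs '<kind> <path>', got {value!r}")
        case.subjects.append(Subject(kind=parts[0], path=parts[1], post_path=post))
    elif key == "script":
        try:
            case.script_command = shlex.split(value)
        except ValueError as e:
            raise err(f"bad script line: {e}") from e
    elif key.startswith("input."):
        case.input_payload[key[len("input."):]] = value
    elif key == "gold":
        parts = value.split(None, 1)
        if len(parts) != 2:
            raise err(f"gold needs '<subject path> <file>', got {value!r}")
        case.gold_standard_refs[parts[0]] = parts[1]
    else:
        raise err(f"unknown case directive {key!r}")


# ---------------------------------------------------------------------------
# JSON equivalent

def _from_json(text: str, path: Path) -> TestProtocol:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ProtocolError(f"{path}: invalid JSON: {e}") from e
    opts = doc.get("options", {})
    known = {"output_dir", "timeout", "options", "cases"}
    for k in doc:
        if k not in known:
            raise ProtocolError(f"{path}: unknown key {k!r}")
    protocol = TestProtocol(
        output_dir=doc.get("output_dir", "plansnap_out"),
        timeout=float(doc.get("timeout", DEFAULT_TIMEOUT)),
        options=CompareOptions(
            numeric_tolerance={k: float(v) for k, v in opts.get("tolerance", {}).items()},
            ignore_paths=list(opts.get("ignore", [])),
            rename_similarity_threshold=float(opts.get("rename_threshold", 0.5)),
            detect_renames=bool(opts.get("detect_renames", True)),
        ),
    )
    for cd in doc.get("cases", []):
        case = TestCase(
            case_id=str(cd.get("case_id", "")),
            store_dir=str(cd.get("store", "")),
            script_command=list(cd.get("script", [])),
            input_payload={k: str(v) for k, v in cd.get("input", {}).items()},
            gold_standard_refs={k: str(v) for k, v in cd.get("gold", {}).items()},
        )
        for sd in cd.get("subjects", []):
            case.subjects.append(
                Subject(kind=sd["kind"], path=sd["path"], post_path=sd.get("post_path"))
            )
        protocol.cases.append(case)
    try:
        return _validate(protocol)
    except ProtocolError as e:
        raise ProtocolError(f"{path}: {e}") from e
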