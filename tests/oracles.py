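"""Independent oracles used by the test suite.

Everything here is deliberately naive and implemented without reference to
the code paths it checks: a brute-force dataclass flattener for model
equality/locality, a snapshot-leaf flattener plus a reconstruction check for
the diff engine, an exhaustive assignment matcher for rename pairing, and a
Monte-Carlo polygon-area estimator.
"""

from __future__ import annotations

import dataclasses
from itertools import permutations
from typing import Dict, List, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# Model flattening (exhaustive field enumeration)

def flatten_model(obj, prefix="") -> Dict[str, str]:
    """Every (path, repr(value)) pair of a dataclass tree, lists by index."""
    out: Dict[str, str] = {}
    if dataclasses.is_dataclass(obj):
        for f in dataclasses.fields(obj):
            out.update(flatten_model(getattr(obj, f.name), f"{prefix}{f.name}/"))
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            out.update(flatten_model(item, f"{prefix}{i}/"))
    else:
        out[prefix.rstrip("/")] = repr(obj)
    return out


def model_diff_paths(a, b) -> set:
    """Symmetric difference of flattened models, as a set of paths."""
    fa, fb = flatten_model(a), flatten_model(b)
    return {p for p in fa.keys() | fb.keys() if fa.get(p) != fb.get(p)}


# ---------------------------------------------------------------------------
# Snapshot-leaf flattening and diff reconstruction

def flatten_tree(node, prefix="") -> Dict[str, str]:
    """(path, value) for every scalar leaf under a FieldNode; the node's own
    key is excluded from paths (as in diff paths)."""
    out: Dict[str, str] = {}
    if node.kind == "scalar":
        out[prefix.rstrip("/")] = node.value or ""
        return out
    for c in node.children:
        if c.kind == "scalar":
            out[f"{prefix}{c.key}"] = c.value or ""
        else:
            out.update(flatten_tree(c, f"{prefix}{c.key}/"))
    return out


def subtree_at(node, path: str):
    """The FieldNode at a slash path below *node*, or None."""
    cur = node
    for seg in [s for s in path.split("/") if s]:
        cur = next((c for c in cur.children if c.key == seg), None)
        if cur is None:
            return None
    return cur


def _under(path: str, prefix: str) -> bool:
    return path == prefix or path.startswith(prefix + "/")


def check_report_against_leaves(before_root, after_root, report) -> List[str]:
    """Verify a ComparisonReport exactly explains the leaf-set transformation
    between two snapshot trees. Returns a list of violation strings (empty if
    the report is the true flatten-and-set-compare diff, rename folding
    accounted).

    Diff paths are before-keyed; rename differences are prefix substitutions
    applied deepest-first to map after-leaf paths into before-keyed space.
    """
    problems: List[str] = []
    before = flatten_tree(before_root)
    after = flatten_tree(after_root)

    renames = [(d.path, d) for d in report.differences if d.change == "renamed"]
    # map after-keyed path -> before-keyed path (apply inverse substitutions
    # shallowest-first so nested renames compose)
    subs = []  # (after_prefix, before_prefix)
    for path, d in sorted(renames, key=lambda x: x[0].count("/")):
        typ = d.path.rsplit("/", 1)[-1].split("[")[0]
        parent = d.path.rsplit("/", 1)[0] if "/" in d.path else ""
        before_key = f"{typ}[{d.before}]"
        after_key = f"{typ}[{d.after}]"
        after_prefix = (parent + "/" if parent else "") + after_key
        # the parent prefix itself may already have been mapped
        for ap, bp in subs:
            if _under(after_prefix, ap):
                after_prefix = bp + after_prefix[len(ap):]
                break
        before_prefix = (parent + "/" if parent else "") + before_key
        if d.path.rsplit("/", 1)[-1] != before_key:
            problems.append(f"rename at {d.path} inconsistent with before={d.before}")
        subs.append((after_prefix, before_prefix))

    def to_before_space(path: str) -> str:
        # apply deepest matching substitution repeatedly
        changed = True
        while changed:
            changed = False
            for ap, bp in sorted(subs, key=lambda s: -len(s[0])):
                if _under(path, ap):
                    path = bp + path[len(ap):]
                    changed = True
                    break
        return path

    after_mapped = {to_before_space(p): v for p, v in after.items()}
    if len(after_mapped) != len(after):
        problems.append("rename substitution collided")

    added = {d.path for d in report.differences if d.change == "added"}
    removed = {d.path for d in report.differences if d.change == "removed"}
    modified = {d.path for d in report.differences if d.change == "modified"}

    only_before = set(before) - set(after_mapped)
    only_after = set(after_mapped) - set(before)
    shared = set(before) & set(after_mapped)

    expect_removed_leaves = {p for p in only_before}
    covered = {p for p in expect_removed_leaves if any(_under(p, r) for r in removed)}
    if covered != expect_removed_leaves:
        problems.append(f"removed leaves unexplained: {expect_removed_leaves - covered}")
    for r in removed:
        if not any(_under(p, r) for p in expect_removed_leaves):
            problems.append(f"spurious removed at {r}")

    covered = {p for p in only_after if any(_under(p, a) for a in added)}
    if covered != only_after:
        problems.append(f"added leaves unexplained: {only_after - covered}")
    for a in added:
        if not any(_under(p, a) for p in only_after):
            problems.append(f"spurious added at {a}")

    true_modified = {p for p in shared if before[p] != after_mapped[p]}
    if modified != true_modified:
        problems.append(
            f"modified mismatch: reported {modified ^ true_modified} differ"
        )
    return problems


# ---------------------------------------------------------------------------
# Exhaustive assignment oracle for rename pairing

def optimal_assignment(before_children, after_children, sim_fn, threshold):
    """Best injective pairing of leftovers maximizing total similarity, by
    exhaustive enumeration (use only for <= 6 elements per side)."""
    best_pairs, best_score = [], -1.0
    nb, na = len(before_children), len(after_children)
    small, large, swapped = (
        (range(nb), after_children, False) if nb <= na else (range(na), before_children, True)
    )
    idx_large = list(range(len(large)))
    for perm in permutations(idx_large, len(list(small))):
        pairs, score = [], 0.0
        for i, j in zip(small, perm):
            b, a = (before_children[i], after_children[j]) if not swapped else (
                before_children[j], after_children[i]
            )
            s = sim_fn(b, a)
            if s >= threshold:
                pairs.append((b.key, a.key))
                score += s
        if score > best_score:
            best_score, best_pairs = score, pairs
    return set(best_pairs), best_score


# ---------------------------------------------------------------------------
# Monte-Carlo polygon area

def monte_carlo_area(points, n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Even-odd point-in-polygon estimate of the area of one polygon (mm^2)."""
    rng = np.random.default_rng(seed)
    pts = np.asarray(points, dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = hi - lo
    samples = lo + rng.random((n_samples, 2)) * span
    x, y = samples[:, 0], samples[:, 1]
    inside = np.zeros(n_samples, dtype=bool)
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return float(inside.mean() * span[0] * span[1])
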