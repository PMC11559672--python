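"""Cross-sample and cross-condition intersection of HBS sets.

Produces the comparison tables the pipeline reports: per-sample HBS sizes,
every pairwise intersection, the k-way common set within a condition, and
the pre/post overlap per sample and globally.  All member lists are emitted
sorted so reports diff cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "HBSSet",
    "IntersectionReport",
    "CrossConditionReport",
    "intersect_hbs",
    "cross_condition_overlap",
]


@dataclass(frozen=True)
class HBSSet:
    """The HBS members of one sample/condition network."""

    sample_id: str
    condition: str
    members: frozenset[str]


@dataclass(frozen=True)
class IntersectionReport:
    """Pairwise and k-way HBS intersections within one condition."""

    condition: str
    sizes: Mapping[str, int]  # sample -> |HBS|
    pairwise: Mapping[tuple[str, str], tuple[str, ...]]  # sorted sample pair -> members
    common: tuple[str, ...]  # k-way intersection, sorted

    def pairwise_sizes(self) -> dict[tuple[str, str], int]:
        return {pair: len(members) for pair, members in self.pairwise.items()}

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "sizes": dict(sorted(self.sizes.items())),
            "pairwise": {
                f"{a}&{b}": list(members)
                for (a, b), members in sorted(self.pairwise.items())
            },
            "common": list(self.common),
        }


def intersect_hbs(
    sets: Sequence[HBSSet], condition: str | None = None
) -> IntersectionReport:
    """All pairwise and the full k-way intersection of same-condition HBS sets.

    Requires at least two sets sharing one condition; the report is
    symmetric in sample order and every member list is sorted.
    """
    if len(sets) < 2:
        raise ValueError(f"need at least 2 HBS sets, got {len(sets)}")
    conditions = {s.condition for s in sets}
    if len(conditions) > 1:
        raise ValueError(
            f"HBS sets mix conditions {sorted(conditions)}; intersect one "
            "condition at a time"
        )
    (found,) = conditions
    if condition is not None and condition != found:
        raise ValueError(
            f"requested condition {condition!r} but sets carry {found!r}"
        )
    by_sample = {s.sample_id: s.members for s in sets}
    if len(by_sample) != len(sets):
        raise ValueError("duplicate sample_id among HBS sets")

    pairwise = {
        tuple(sorted((a, b))): tuple(sorted(by_sample[a] & by_sample[b]))
        for a, b in combinations(sorted(by_sample), 2)
    }
    common = frozenset.intersection(*by_sample.values())
    return IntersectionReport(
        condition=found,
        sizes={sid: len(members) for sid, members in by_sample.items()},
        pairwise=pairwise,
        common=tuple(sorted(common)),
    )


@dataclass(frozen=True)
class CrossConditionReport:
    """Pre/post HBS overlap per sample plus the global six-set intersection."""

    per_sample: Mapping[str, tuple[str, ...]]  # sample -> sorted pre&post members
    global_common: tuple[str, ...]  # intersection over all sets, both conditions

    def to_dict(self) -> dict:
        return {
            "per_sample": {
                sid: list(members)
                for sid, members in sorted(self.per_sample.items())
            },
            "global_common": list(self.global_common),
        }


def cross_condition_overlap(
    pre_sets: Sequence[HBSSet], post_sets: Sequence[HBSSet]
) -> CrossConditionReport:
    """Per-sample pre/post overlap and the intersection over all sets.

    Sample identifiers must match one-to-one between conditions.
    """
    pre = {s.sample_id: s.members for s in pre_sets}
    post = {s.sample_id: s.members for s in post_sets}
    if set(pre) != set(post):
        raise ValueError(
            f"unmatched samples: pre={sorted(pre)}, post={sorted(post)}"
        )
    per_sample = {
        sid: tuple(sorted(pre[sid] & post[sid])) for sid in sorted(pre)
    }
    global_common = frozenset.intersection(*pre.values(), *post.values())
    return CrossConditionReport(
        per_sample=per_sample,
        global_common=tuple(sorted(global_common)),
    )


def write_comparison(
    reports: Mapping[str, IntersectionReport],
    cross: CrossConditionReport,
    json_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Serialize comparison reports as JSON (and optionally TSV blocks)."""
    payload = {
        "conditions": {c: r.to_dict() for c, r in sorted(reports.items())},
        "cross_condition": cross.to_dict(),
    }
    Path(json_path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    if tsv_path is not None:
        lines = []
        for cond, report in sorted(reports.items()):
            lines.append(f"# condition={cond}")
            for sid, size in sorted(report.sizes.items()):
                lines.append(f"hbs_size\t{sid}\t{size}")
            for (a, b), members in sorted(report.pairwise.items()):
                lines.append(f"pairwise\t{a}&{b}\t{len(members)}\t{','.join(members)}")
            lines.append(
                f"common\tall\t{len(report.common)}\t{','.join(report.common)}"
            )
        lines.append("# cross_condition")
        for sid, members in sorted(cross.per_sample.items()):
            lines.append(f"pre_post\t{sid}\t{len(members)}\t{','.join(members)}")
        lines.append(
            "global\tall\t"
            f"{len(cross.global_common)}\t{','.join(cross.global_common)}"
        )
        Path(tsv_path).write_text("\n".join(lines) + "\n")
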