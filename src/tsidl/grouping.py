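"""Confusion-driven grouping of visually similar classes.

The stage-1 classifier's cross-validated confusion matrix (CVCM) exposes
which classes it systematically mixes up.  The grouping algorithm scans the
validation CVCM and builds a *similarity-group map* (SG map):

1. flag every class whose diagonal count (TP) falls at or below a threshold
   ("red" classes — the classifier misses them too often);
2. for each red class, collect the classes its misses land on — the
   off-diagonal entries of its row at or above the FN threshold ("yellow"
   partners);
3. within each coarse package class, union the red classes and their
   same-package yellow partners into one similar-drug (SD) list — an SD list
   never mixes package classes, since cross-package confusions are package
   errors, not lookalike errors;
4. SD lists with at least two members become the ordered similarity groups
   SG1..SGN (lexicographic by package class); every other class falls into
   the residual group SG_{N+1}.

With the reference protocol each class has validation support 50 (5 folds x
10 validation images), and the default thresholds are absolute counts:
TP <= 48 flags a class, FN >= 1 flags a partner.  For datasets whose support
differs, a relative mode derives the TP cut per class as
``floor(tp_fraction * support_i)`` (default fraction 48/50 = 0.96).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .confmat import ConfusionMatrix

logger = logging.getLogger(__name__)

__all__ = ["GroupingParams", "SDList", "SGMap", "find_similar_groups", "assign_group"]


@dataclass(frozen=True)
class GroupingParams:
    """Thresholds steering the grouping scan.

    tp_threshold/fn_threshold are absolute counts (mode="absolute", the
    default, matching validation support 50).  mode="relative" instead flags
    class i when TP_i <= floor(tp_fraction * support_i).
    """

    tp_threshold: int = 48
    fn_threshold: int = 1
    support: int = 50
    mode: str = "absolute"  # "absolute" | "relative"
    tp_fraction: float = 0.96
    scan_columns: bool = False  # also scan FP (column) partners
    connected_components: bool = False  # split per-package union into components

    def __post_init__(self) -> None:
        if not (0 <= self.tp_threshold <= self.support):
            raise ValueError("tp_threshold must lie in [0, support]")
        if self.fn_threshold < 1:
            raise ValueError("fn_threshold must be >= 1")
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.tp_fraction <= 1):
            raise ValueError("tp_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SDList:
    """Similar-drug list: >=2 fine labels confined to one package class."""

    package_class: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise ValueError(
                f"SD list for {self.package_class!r} needs >=2 members, "
                f"got {sorted(self.members)}"
            )


@dataclass(frozen=True)
class SGMap:
    """Similarity-group map: ordered SD lists plus the residual group.

    Groups are indexed 1..N; the residual is index N+1.  Together they
    partition the full fine-label set — the routing contract for stage 2.
    """

    groups: tuple[SDList, ...]
    residual: frozenset[str]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "residual", frozenset(self.residual))
        seen: set[str] = set()
        for g in self.groups:
            if g.members & seen:
                raise ValueError(f"labels {sorted(g.members & seen)} in two groups")
            seen |= g.members
        if seen & self.residual:
            raise ValueError(
                f"labels {sorted(seen & self.residual)} both grouped and residual"
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def residual_index(self) -> int:
        return len(self.groups) + 1

    def all_labels(self) -> frozenset[str]:
        out = set(self.residual)
        for g in self.groups:
            out |= g.members
        return frozenset(out)

    def members_of(self, index: int) -> frozenset[str]:
        if 1 <= index <= len(self.groups):
            return self.groups[index - 1].members
        if index == self.residual_index:
            return self.residual
        raise KeyError(f"no group with index {index}")

    # -- serialization (the routing contract consumed by the pipeline) ------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "groups": [
                {"package_class": g.package_class, "members": sorted(g.members)}
                for g in self.groups
            ],
            "residual": sorted(self.residual),
            "provenance": dict(self.provenance),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SGMap":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            groups=tuple(
                SDList(g["package_class"], frozenset(g["members"]))
                for g in d["groups"]
            ),
            residual=frozenset(d["residual"]),
            provenance=d.get("provenance", {}),
        )


def _red_labels(cvcm: ConfusionMatrix, params: GroupingParams) -> list[str]:
    tp = cvcm.tp()
    support = cvcm.support()
    red = []
    for i, lab in enumerate(cvcm.labels):
        if params.mode == "relative":
            cut = int(params.tp_fraction * support[i])
        else:
            cut = params.tp_threshold
        if tp[i] <= cut:
            red.append(lab)
    return red


def find_similar_groups(
    cvcm: ConfusionMatrix,
    package_of: Mapping[str, str],
    params: GroupingParams = GroupingParams(),
) -> SGMap:
    """Scan a validation CVCM for confusable classes and build the SG map.

    Yellow partners are read from the red class's ROW (its FN destinations)
    only, unless ``params.scan_columns`` also enables FP (column) partners.
    Cross-package partners are excluded with a warning; a red class left
    without any same-package partner dissolves into the residual group.
    """
    if cvcm.r == 0:
        raise ValueError("confusion matrix has no classes")
    for lab in cvcm.labels:
        if lab not in package_of:
            raise KeyError(f"label {lab!r} missing from the package map")

    red = _red_labels(cvcm, params)
    counts = cvcm.counts

    # red class -> same-package partner set
    partners: dict[str, set[str]] = {}
    for lab in red:
        i = cvcm.index_of(lab)
        yellow: set[str] = set()
        for j, other in enumerate(cvcm.labels):
            if j == i:
                continue
            hit = counts[i, j] >= params.fn_threshold
            if params.scan_columns:
                hit = hit or counts[j, i] >= params.fn_threshold
            if not hit:
                continue
            if package_of[other] != package_of[lab]:
                logger.warning(
                    "cross-package partner %r (package %s) of red class %r "
                    "(package %s) excluded from the SD list",
                    other,
                    package_of[other],
                    lab,
                    package_of[lab],
                )
                continue
            yellow.add(other)
        partners[lab] = yellow

    # per-package union of red classes and their same-package partners
    per_package: dict[str, set[str]] = {}
    for lab, yellow in partners.items():
        per_package.setdefault(package_of[lab], set()).update({lab} | yellow)

    sd_lists: list[SDList] = []
    dissolved: set[str] = set()
    for pkg in sorted(per_package):
        members = per_package[pkg]
        if params.connected_components:
            comps = _components(members, partners)
        else:
            comps = [members]
        for comp in comps:
            if len(comp) >= 2:
                sd_lists.append(SDList(pkg, frozenset(comp)))
            else:
                dissolved |= comp
                logger.warning(
                    "singleton SD list %s in package %s dissolved into the residual",
                    sorted(comp),
                    pkg,
                )

    grouped = set().union(*(g.members for g in sd_lists)) if sd_lists else set()
    residual = frozenset(set(cvcm.labels) - grouped)
    return SGMap(
        groups=tuple(sd_lists),
        residual=residual,
        provenance={
            "tp_threshold": params.tp_threshold,
            "fn_threshold": params.fn_threshold,
            "mode": params.mode,
            "tp_fraction": params.tp_fraction,
            "cvcm_digest": cvcm.digest(),
            "red": sorted(red),
            "dissolved_singletons": sorted(dissolved),
        },
    )


def _components(members: set[str], partners: Mapping[str, set[str]]) -> list[set[str]]:
    """Connected components of the red->yellow adjacency, restricted to members."""
    adj: dict[str, set[str]] = {m: set() for m in members}
    for red, yellow in partners.items():
        if red not in members:
            continue
        for y in yellow & members:
            adj[red].add(y)
            adj[y].add(red)
    comps, todo = [], set(members)
    while todo:
        stack = [todo.pop()]
        comp = set(stack)
        while stack:
            for n in adj[stack.pop()] & todo:
                todo.discard(n)
                comp.add(n)
                stack.append(n)
        comps.append(comp)
    return sorted(comps, key=lambda c: sorted(c)[0])


def assign_group(label: str, sg_map: SGMap) -> int:
    """Route a fine label to its similarity-group index (residual = N+1)."""
    for k, g in enumerate(sg_map.groups, start=1):
        if label in g.members:
            return k
    if label in sg_map.residual:
        return sg_map.residual_index
    raise KeyError(f"label {label!r} not present in the SG map")
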