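"""Unsupervised correlation-based feature reduction (CFR) and feature groups.

Both CFR variants iteratively inspect the most correlated remaining feature
pair (|correlation| above the cutoff) and discard one member:

* **standard** — the member with the higher mean absolute correlation to all
  other remaining features is discarded (the rule popularised by caret's
  ``findCorrelation``);
* **hierarchical** — if the two features sit at different levels of an
  interpretability hierarchy (default ``MeshVolume > shape > first-order >
  texture``), the lower-ranked feature is discarded; within a level the
  standard rule applies.  MeshVolume occupies its own top level and is
  therefore never discarded in favour of anything else.

Candidate feature groups — the tuning grid of the supervised group-selection
step — are the four base groups (MeshVolume; shape including MeshVolume;
first-order; texture) plus all pairwise unions of the three classes and the
full set: eight groups for the default registry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features.extract import FeatureTable
from .features.registry import FeatureKey

DEFAULT_HIERARCHY = ("MeshVolume", "shape", "firstorder", "texture")

GROUP_NAMES = (
    "MeshVolume",
    "shape",
    "firstorder",
    "texture",
    "shape+firstorder",
    "shape+texture",
    "firstorder+texture",
    "all",
)


@dataclass
class CfrConfig:
    cutoff: float = 0.90
    method: str = "spearman"  # or "pearson"
    mode: str = "standard"  # or "hierarchical"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        if self.method not in {"spearman", "pearson"}:
            raise ValueError(f"unknown correlation method: {self.method}")
        if self.mode not in {"standard", "hierarchical"}:
            raise ValueError(f"unknown CFR mode: {self.mode}")


@dataclass
class GroupHierarchy:
    """Ordered interpretability levels, highest (most interpretable) first."""

    levels: tuple[str, ...] = DEFAULT_HIERARCHY

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("hierarchy labels must be unique")

    def level_of(self, key: FeatureKey) -> int:
        """Rank index of a feature; lower index = higher interpretability."""
        label = "MeshVolume" if key.is_mesh_volume else key.feature_class
        try:
            return self.levels.index(label)
        except ValueError:
            raise KeyError(f"feature {key} maps to no hierarchy level") from None


def correlation_matrix(table: FeatureTable, method: str = "spearman") -> np.ndarray:
    """Symmetric feature–feature correlation matrix with unit diagonal."""
    x = table.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    sds = x.std(axis=0)
    if np.any(sds == 0):
        bad = [str(k) for k, s in zip(table.keys(), sds) if s == 0]
        raise ValueError(f"constant feature columns: {bad}")
    if method == "spearman":
        corr = stats.spearmanr(x).statistic
        corr = np.atleast_2d(corr)
    elif method == "pearson":
        corr = np.corrcoef(x, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method: {method}")
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CfrAudit:
    """One discard decision; serialized as a JSON line in the audit log."""

    pair: tuple[str, str]
    correlation: float
    rule: str  # "standard" | "hierarchy"
    discarded: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "pair": list(self.pair),
                "correlation": self.correlation,
                "rule": self.rule,
                "discarded": self.discarded,
            }
        )


def _cfr_loop(
    keys: list[FeatureKey],
    corr: np.ndarray,
    cutoff: float,
    choose_discard,
) -> tuple[list[FeatureKey], list[CfrAudit]]:
    """Iteratively discard from the most correlated remaining pair.

    ``choose_discard(i, j, active, abs_corr)`` returns (index_to_drop, rule).
    Ties on pair correlation break lexicographically on the key pair.
    """
    abs_corr = np.abs(np.asarray(corr, dtype=float))
    np.fill_diagonal(abs_corr, 0.0)
    active = list(range(len(keys)))
    audit: list[CfrAudit] = []
    while len(active) > 1:
        sub = abs_corr[np.ix_(active, active)]
        m = sub.max()
        if m <= cutoff:
            break
        cand = np.argwhere(np.isclose(sub, m))
        pairs = sorted(
            {
                tuple(sorted((active[a], active[b])))
                for a, b in cand
                if a != b
            },
            key=lambda ij: (str(keys[ij[0]]), str(keys[ij[1]])),
        )
        i, j = pairs[0]
        drop, rule = choose_discard(i, j, active, abs_corr)
        keep = j if drop == i else i
        audit.append(
            CfrAudit(
                pair=(str(keys[i]), str(keys[j])),
                correlation=float(corr[i, j]),
                rule=rule,
                discarded=str(keys[drop]),
            )
        )
        active.remove(drop)
    return [keys[i] for i in active], audit


def _standard_rule(keys: list[FeatureKey]):
    def choose(i: int, j: int, active: list[int], abs_corr: np.ndarray):
        others_i = [a for a in active if a != i]
        others_j = [a for a in active if a != j]
        mean_i = abs_corr[i, others_i].mean()
        mean_j = abs_corr[j, others_j].mean()
        if np.isclose(mean_i, mean_j):
            drop = max(i, j, key=lambda t: str(keys[t]))
        else:
            drop = i if mean_i > mean_j else j
        return drop, "standard"

    return choose


def standard_cfr(
    table: FeatureTable, config: CfrConfig | None = None
) -> tuple[list[FeatureKey], list[CfrAudit]]:
    """Standard CFR: discard the pair member with higher mean |correlation|."""
    config = config or CfrConfig(mode="standard")
    keys = table.keys()
    corr = correlation_matrix(table, config.method)
    return _cfr_loop(keys, corr, config.cutoff, _standard_rule(keys))


def hierarchical_cfr(
    table: FeatureTable,
    config: CfrConfig | None = None,
    hierarchy: GroupHierarchy | None = None,
) -> tuple[list[FeatureKey], list[CfrAudit]]:
    """Hierarchical CFR: cross-level pairs discard the lower-ranked feature."""
    config = config or CfrConfig(mode="hierarchical")
    hierarchy = hierarchy or GroupHierarchy()
    keys = table.keys()
    for k in keys:
        hierarchy.level_of(k)  # raises on unmapped features
    corr = correlation_matrix(table, config.method)
    standard = _standard_rule(keys)

    def choose(i: int, j: int, active: list[int], abs_corr: np.ndarray):
        li, lj = hierarchy.level_of(keys[i]), hierarchy.level_of(keys[j])
        if li == lj:
            return standard(i, j, active, abs_corr)
        return (i if li > lj else j), "hierarchy"

    return _cfr_loop(keys, corr, config.cutoff, choose)


def write_audit_log(audit: list[CfrAudit], path: str) -> None:
    with open(path, "w") as fh:
        for rec in audit:
            fh.write(rec.to_json() + "\n")


# ---------------------------------------------------------------------------
# Candidate feature groups


@dataclass
class CandidateGroupSet:
    """The named feature subsets used as the group-selection tuning grid."""

    groups: dict[str, list[FeatureKey]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def __getitem__(self, name: str) -> list[FeatureKey]:
        return self.groups[name]

    def __len__(self) -> int:
        return len(self.groups)


def _members(keys: list[FeatureKey], classes: set[str], mesh_only: bool = False):
    if mesh_only:
        return [k for k in keys if k.is_mesh_volume]
    return [k for k in keys if k.feature_class in classes]


def candidate_group_definitions(classes: tuple[str, ...]) -> list[tuple[str, set[str] | None]]:
    """Group construction law for k feature classes: the volume singleton,
    each class, all pairwise class unions, and the full set — 2 + k + k(k-1)/2
    groups (8 for the default three classes)."""
    defs: list[tuple[str, set[str] | None]] = [("MeshVolume", None)]
    defs += [(c, {c}) for c in classes]
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            defs.append((f"{classes[a]}+{classes[b]}", {classes[a], classes[b]}))
    defs.append(("all", set(classes)))
    return defs


def enumerate_candidate_groups(
    keys: list[FeatureKey], classes: tuple[str, ...] = ("shape", "firstorder", "texture")
) -> CandidateGroupSet:
    """Materialize the candidate groups (eight by default) from FeatureKeys.

    Group membership follows feature class irrespective of ROI, and the shape
    group includes MeshVolume.  Groups left empty (e.g. a class eliminated by
    CFR) are excluded from the grid with a warning.
    """
    out = CandidateGroupSet()
    for name, class_set in candidate_group_definitions(classes):
        if class_set is None:
            members = _members(keys, set(), mesh_only=True)
        else:
            members = _members(keys, class_set)
        if members:
            out.groups[name] = members
        else:
            out.warnings.append(f"group '{name}' is empty and excluded from the grid")
    return out


def subset_features(table: FeatureTable, group_set: CandidateGroupSet, name: str) -> FeatureTable:
    """Restrict a table's columns to one candidate group."""
    if name not in group_set.groups:
        raise KeyError(f"unknown or empty group: {name}")
    return table.subset(group_set[name])
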