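"""Pair construction, control-group semantics, effective sample size and
pairwise QC.

A pair couples a gRNA group (a singleton gRNA or a site-level group of gRNAs)
to a response.  Treatment cells carry the group's gRNAs; control cells are
either the remaining non-targeting (NT) cells or the complement set of all
other cells.  The effective sample size (ESS) of a pair is the number of
treatment cells with nonzero expression of the response; pairs below the ESS
threshold (default 7) are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import ScreenDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PairSpec",
    "DEFAULT_ESS_MIN",
    "resolve_cells",
    "effective_sample_size",
    "pairwise_qc",
    "build_discovery_pairs",
    "build_negative_control_pairs",
    "build_positive_control_pairs",
]

DEFAULT_ESS_MIN = 7


@dataclass(frozen=True)
class PairSpec:
    grna_group: str
    response_id: str
    pair_type: str = "discovery"  # discovery | negative_control | positive_control
    control_group: str = "nt_cells"  # nt_cells | complement

    @property
    def pair_id(self) -> str:
        return f"{self.grna_group}|{self.response_id}"


def _group_cells(ds: ScreenDataset, grna_group: str) -> np.ndarray:
    grnas = set(ds.grna_table.index[ds.grna_table["grna_group"] == grna_group])
    if not grnas:
        raise KeyError(f"unknown gRNA group {grna_group!r}")
    vec = ds.assignment_vector()
    return np.flatnonzero(np.isin(vec, list(grnas)))


def _nt_cells(ds: ScreenDataset) -> np.ndarray:
    nt = ds.nt_grna_ids()
    vec = ds.assignment_vector()
    return np.flatnonzero(np.isin(vec, nt))


def resolve_cells(ds: ScreenDataset, spec: PairSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sorted, disjoint (treatment, control) cell index sets for a pair.

    NT-cells mode: control = NT cells minus treatment (for a negative-control
    pair on NT gRNA i this is exactly the other NT cells).  Complement mode:
    control = every cell not in treatment.
    """
    treatment = _group_cells(ds, spec.grna_group)
    if spec.control_group == "nt_cells":
        control = np.setdiff1d(_nt_cells(ds), treatment)
    elif spec.control_group == "complement":
        control = np.setdiff1d(np.arange(ds.n_cells), treatment)
    else:
        raise ValueError(f"unknown control group {spec.control_group!r}")
    return np.sort(treatment), np.sort(control)


def effective_sample_size(ds: ScreenDataset, spec: PairSpec) -> int:
    """Treatment cells with nonzero expression of the pair's response."""
    treatment, _ = resolve_cells(ds, spec)
    y = ds.response_row(spec.response_id)
    return int(np.count_nonzero(y[treatment]))


def pairwise_qc(
    pairs: list[PairSpec],
    ds: ScreenDataset,
    ess_min: int = DEFAULT_ESS_MIN,
) -> tuple[list[PairSpec], list[tuple[PairSpec, str]]]:
    """Keep pairs with ESS >= ess_min; return removals with reasons.

    Cell resolution and per-response nonzero counts are computed once per
    gRNA group, so screening all group x response candidates stays cheap.
    """
    import scipy.sparse as sp

    kept: list[PairSpec] = []
    removed: list[tuple[PairSpec, str]] = []
    resp_pos = {r: i for i, r in enumerate(ds.response_ids)}
    cells_cache: dict[tuple[str, str], tuple] = {}
    ess_cache: dict[str, np.ndarray] = {}
    for spec in pairs:
        ckey = (spec.grna_group, spec.control_group)
        if ckey not in cells_cache:
            try:
                cells_cache[ckey] = resolve_cells(ds, spec)
            except KeyError as exc:
                cells_cache[ckey] = (None, str(exc))
        treatment, control = cells_cache[ckey]
        if treatment is None:
            removed.append((spec, f"unresolvable: {control}"))
            continue
        if len(treatment) == 0:
            removed.append((spec, "empty treatment group"))
            continue
        if len(control) == 0:
            removed.append((spec, "empty control group"))
            continue
        if spec.grna_group not in ess_cache:
            sub = ds.counts[:, treatment]
            if sp.issparse(sub):
                ess_cache[spec.grna_group] = sub.getnnz(axis=1)
            else:
                ess_cache[spec.grna_group] = np.count_nonzero(sub > 0, axis=1)
        ess = int(ess_cache[spec.grna_group][resp_pos[spec.response_id]])
        if ess < ess_min:
            removed.append((spec, f"ess {ess} < {ess_min}"))
        else:
            kept.append(spec)
    return kept, removed


def build_discovery_pairs(
    ds: ScreenDataset, control_group: str = "nt_cells"
) -> list[PairSpec]:
    """Default discovery set: every targeting gRNA group x every response."""
    groups = sorted(
        ds.grna_table.loc[ds.grna_table["targeting"].astype(bool), "grna_group"].unique()
    )
    return [
        PairSpec(g, r, "discovery", control_group)
        for g in groups
        for r in ds.response_ids
    ]


def _nt_groups(ds: ScreenDataset, grouped: bool, discovery_pairs: list[PairSpec], rng) -> dict[str, list[str]]:
    """Map negative-control group label -> member NT gRNA ids."""
    nt = sorted(ds.nt_grna_ids())
    if not grouped:
        return {g: [g] for g in nt}
    # sample group sizes from the discovery groups' empirical size distribution
    sizes = (
        ds.grna_table.loc[ds.grna_table["targeting"].astype(bool)]
        .groupby("grna_group")
        .size()
        .to_numpy()
    )
    if sizes.size == 0:
        sizes = np.array([1])
    order = rng.permutation(len(nt))
    groups: dict[str, list[str]] = {}
    pos = 0
    k = 0
    while pos < len(nt):
        size = int(rng.choice(sizes))
        members = [nt[i] for i in order[pos : pos + size]]
        groups[f"ntgroup_{k}"] = members
        pos += size
        k += 1
    return groups


def build_negative_control_pairs(
    ds: ScreenDataset,
    discovery_pairs: list[PairSpec],
    grouped: bool = False,
    seed: int = 0,
    ess_min: int = DEFAULT_ESS_MIN,
    control_group: str = "nt_cells",
) -> list[PairSpec]:
    """NT-gRNA x response pairs matched to the discovery set.

    Candidates are all (NT gRNA or NT group) x response pairs; the same
    pairwise QC as the discovery pairs is applied; the surviving candidates
    are uniformly subsampled (seeded) down to the discovery-pair count.  The
    matching requires the NT units to form valid groups, which is what makes
    the resulting p-value distribution a calibration reference.
    """
    rng = np.random.default_rng(seed)
    nt = ds.nt_grna_ids()
    if control_group == "nt_cells" and len(nt) < 2:
        raise ValueError("NT-cells control mode needs at least 2 NT gRNAs")
    groups = _nt_groups(ds, grouped, discovery_pairs, rng)

    # NT pairs are built against dedicated group labels; temporarily register
    # grouped labels in a copy of the metadata
    ds_nc = ds
    if grouped:
        table = ds.grna_table.copy()
        for label, members in groups.items():
            table.loc[members, "grna_group"] = label
        from dataclasses import replace

        ds_nc = replace(ds, grna_table=table)

    candidates = [
        PairSpec(label, r, "negative_control", control_group)
        for label in sorted(groups)
        for r in ds.response_ids
    ]
    kept, _ = pairwise_qc(candidates, ds_nc, ess_min=ess_min)
    n_target = len(discovery_pairs)
    if len(kept) < n_target:
        logger.warning(
            "only %d negative-control candidates survive QC (< %d discovery pairs)",
            len(kept),
            n_target,
        )
        return kept
    pick = np.sort(rng.choice(len(kept), size=n_target, replace=False))
    return [kept[i] for i in pick]


def build_positive_control_pairs(
    ds: ScreenDataset, control_group: str = "nt_cells"
) -> list[PairSpec]:
    """One pair per targeting group whose target label is a response id.

    Matching is exact string equality after case normalization; a target label
    matching several response ids is an error.
    """
    responses = {str(r).casefold(): r for r in ds.response_ids}
    if len(responses) != len(ds.response_ids):
        raise ValueError("response ids are ambiguous after case normalization")
    targeting = ds.grna_table[ds.grna_table["targeting"].astype(bool)]
    pairs: list[PairSpec] = []
    for group, sub in targeting.groupby("grna_group"):
        targets = {str(t).casefold() for t in sub["target"].dropna().unique()}
        hits = sorted(t for t in targets if t in responses)
        if len(hits) > 1:
            raise ValueError(f"gRNA group {group!r} matches multiple responses: {hits}")
        if hits:
            pairs.append(PairSpec(str(group), responses[hits[0]], "positive_control", control_group))
    if not pairs:
        logger.warning("no positive-control pairs found")
    return pairs
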