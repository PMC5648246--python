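"""Barcode-gap analysis.

For each sequence we compute the distance to its *furthest conspecific* and
to its *nearest neighbor* (closest sequence of a different species).  A
species with two or more members shows a barcode gap when every member's
nearest-neighbor distance exceeds that member's maximum conspecific
distance.  The module also pools distances into intraspecific and congeneric
summaries and derives the empirical thresholds used by the identification
simulations: the 95th percentile of intraspecific distances and the 5th
percentile of congeneric distances (linear interpolation between closest
ranks, numpy's default percentile rule; the rule is fixed and used
everywhere).

Unlabeled records (no species name) are excluded from every pool and from
nearest-neighbor consideration: they cannot be scored correct or incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = [
    "GapProfile",
    "DivergenceSummary",
    "divergence_summaries",
    "intraspecific_pool",
    "congeneric_pool",
    "gap_profile",
    "empirical_thresholds",
    "assess_singletons",
]


def _label_arrays(dm: DistanceMatrix, labels: Mapping[str, str]) -> np.ndarray:
    """Species label per matrix row; '' marks unlabeled."""
    return np.array([labels.get(sid, "") or "" for sid in dm.ids], dtype=object)


def intraspecific_pool(dm: DistanceMatrix, labels: Mapping[str, str]) -> np.ndarray:
    """All conspecific pairwise distances (species with >= 2 members)."""
    lab = _label_arrays(dm, labels)
    iu = np.triu_indices(len(dm.ids), k=1)
    same = (lab[iu[0]] == lab[iu[1]]) & (lab[iu[0]] != "")
    vals = dm.d[iu][same]
    return vals[~np.isnan(vals)]


def congeneric_pool(
    dm: DistanceMatrix, labels: Mapping[str, str], genus: Mapping[str, str]
) -> np.ndarray:
    """Distances between individuals of different species of the same genus."""
    lab = _label_arrays(dm, labels)
    gen = np.array([genus.get(sid, "") or "" for sid in dm.ids], dtype=object)
    iu = np.triu_indices(len(dm.ids), k=1)
    sel = (
        (lab[iu[0]] != lab[iu[1]])
        & (lab[iu[0]] != "")
        & (lab[iu[1]] != "")
        & (gen[iu[0]] == gen[iu[1]])
        & (gen[iu[0]] != "")
    )
    vals = dm.d[iu][sel]
    return vals[~np.isnan(vals)]


@dataclass
class DivergenceSummary:
    """Pooled intraspecific and congeneric divergence statistics."""

    intraspecific: dict | None
    congeneric: dict | None

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name, stats in (("intraspecific", self.intraspecific), ("congeneric", self.congeneric)):
            if stats is not None:
                rows.append({"pool": name, **stats})
        return pd.DataFrame(rows)


def divergence_summaries(
    dm: DistanceMatrix, labels: Mapping[str, str], genus: Mapping[str, str]
) -> DivergenceSummary:
    """Mean/min/max and comparison counts for both distance pools.

    An empty pool yields ``None`` for that summary, never zeros.
    """
    lab = _label_arrays(dm, labels)
    intra = intraspecific_pool(dm, labels)
    cong = congeneric_pool(dm, labels, genus)

    intra_stats = None
    if intra.size:
        counts = pd.Series(lab[lab != ""]).value_counts()
        multi = counts[counts >= 2]
        gen_of = {labels[sid]: genus.get(sid, "") for sid in dm.ids if labels.get(sid)}
        intra_stats = {
            "mean": float(intra.mean()),
            "min": float(intra.min()),
            "max": float(intra.max()),
            "n_comparisons": int(intra.size),
            "n_species": int(len(multi)),
            "n_genera": int(len({gen_of[s] for s in multi.index if gen_of.get(s)})),
        }
    cong_stats = None
    if cong.size:
        sp_gen = {labels[sid]: genus.get(sid, "") for sid in dm.ids if labels.get(sid)}
        by_genus: dict[str, set[str]] = {}
        for sp, g in sp_gen.items():
            if g:
                by_genus.setdefault(g, set()).add(sp)
        multi_genera = {g: sps for g, sps in by_genus.items() if len(sps) >= 2}
        n_pairs = sum(len(s) * (len(s) - 1) // 2 for s in multi_genera.values())
        cong_stats = {
            "mean": float(cong.mean()),
            "min": float(cong.min()),
            "max": float(cong.max()),
            "n_comparisons": int(cong.size),
            "n_species": int(len(set().union(*multi_genera.values()))) if multi_genera else 0,
            "n_genera": int(len(multi_genera)),
            "n_species_pairs": int(n_pairs),
        }
    return DivergenceSummary(intraspecific=intra_stats, congeneric=cong_stats)


@dataclass
class GapProfile:
    """Per-sequence furthest-conspecific/nearest-neighbor distances and
    per-species barcode-gap verdicts."""

    per_sequence: pd.DataFrame  # specimen_id, species, max_conspecific, nn_distance, nn_taxon
    per_species: pd.DataFrame  # species, n_individuals, gap_present

    def sequences_with_shared_barcodes(self) -> pd.DataFrame:
        return self.per_sequence[self.per_sequence["nn_distance"] == 0.0]


def gap_profile(dm: DistanceMatrix, labels: Mapping[str, str]) -> GapProfile:
    """Furthest-conspecific and nearest-neighbor distance per sequence.

    ``max_conspecific`` is NaN for singletons and unlabeled records;
    unlabeled records are never anyone's nearest neighbor.
    """
    lab = _label_arrays(dm, labels)
    if len(set(lab[lab != ""])) < 2:
        raise ValueError("need at least 2 labeled species")
    n = len(dm.ids)
    d = dm.d
    labeled = lab != ""

    rows = []
    for i in range(n):
        if not labeled[i]:
            continue
        conspecific = (lab == lab[i]) & labeled
        conspecific[i] = False
        hetero = labeled & (lab != lab[i])
        with np.errstate(invalid="ignore"):
            max_con = np.nanmax(d[i, conspecific]) if conspecific.any() else np.nan
            if hetero.any():
                nn_vals = d[i, hetero]
                j_rel = np.nanargmin(nn_vals)
                nn_dist = nn_vals[j_rel]
                nn_taxon = lab[np.flatnonzero(hetero)[j_rel]]
            else:
                nn_dist, nn_taxon = np.nan, ""
        rows.append(
            {
                "specimen_id": dm.ids[i],
                "species": lab[i],
                "max_conspecific": max_con,
                "nn_distance": nn_dist,
                "nn_taxon": nn_taxon,
            }
        )
    per_seq = pd.DataFrame(rows)

    sp_rows = []
    for sp, grp in per_seq.groupby("species", sort=True):
        n_ind = len(grp)
        if n_ind >= 2:
            gap = bool((grp["nn_distance"] > grp["max_conspecific"]).all())
        else:
            gap = None  # undefined for singletons
        sp_rows.append({"species": sp, "n_individuals": n_ind, "gap_present": gap})
    per_species = pd.DataFrame(sp_rows)
    return GapProfile(per_sequence=per_seq, per_species=per_species)


def empirical_thresholds(
    dm: DistanceMatrix, labels: Mapping[str, str], genus: Mapping[str, str]
) -> tuple[float, float]:
    """(95th percentile of intraspecific, 5th percentile of congeneric) distances."""
    intra = intraspecific_pool(dm, labels)
    cong = congeneric_pool(dm, labels, genus)
    if intra.size == 0 or cong.size == 0:
        raise ValueError("empty distance pool; thresholds undefined")
    return float(np.percentile(intra, 95)), float(np.percentile(cong, 5))


def assess_singletons(dm: DistanceMatrix, labels: Mapping[str, str], tree) -> pd.DataFrame:
    """Tree-based distinctiveness of singleton species.

    A singleton is *distinguishable* when (a) its barcode is not shared with
    any non-conspecific (nearest-neighbor distance > 0) and (b) it is not
    nested inside the nearest-neighbor species' subtree: some edge of the
    gene tree (other than the singleton's own tip edge) must separate it
    from every member of that species.

    ``tree`` is an skbio ``TreeNode`` whose tips are the matrix ids.
    """
    lab = _label_arrays(dm, labels)
    tip_names = {t.name for t in tree.tips()}
    counts = pd.Series(lab[lab != ""]).value_counts()
    singletons = [sp for sp in counts.index if counts[sp] == 1]

    prof = gap_profile(dm, labels).per_sequence.set_index("specimen_id")
    rows = []
    for sp in sorted(singletons):
        sid = dm.ids[int(np.flatnonzero(lab == sp)[0])]
        if sid not in tip_names:
            raise ValueError(f"singleton {sid} absent from tree")
        nn_dist = prof.loc[sid, "nn_distance"]
        nn_sp = prof.loc[sid, "nn_taxon"]
        shares = bool(nn_dist == 0.0)
        nested = False
        if not shares and nn_sp:
            nn_ids = [dm.ids[k] for k in np.flatnonzero(lab == nn_sp)]
            nested = not _separated_in_tree(tree, sid, nn_ids)
        rows.append(
            {
                "species": sp,
                "specimen_id": sid,
                "nn_distance": nn_dist,
                "nn_taxon": nn_sp,
                "shares_barcode": shares,
                "nested_in_neighbor": nested,
                "distinguishable": (not shares) and (not nested),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "specimen_id",
            "nn_distance",
            "nn_taxon",
            "shares_barcode",
            "nested_in_neighbor",
            "distinguishable",
        ],
    )


def _separated_in_tree(tree, sid: str, nn_ids: list[str]) -> bool:
    """True when some tree edge parts ``sid`` from every member of the
    neighbor species.

    Equivalently: after pruning the singleton's tip, all neighbor-species
    members lie in a single direction from its attachment node — the
    singleton branches off the *outside* of that species' subtree rather
    than from within it.  The singleton's own tip edge does not count (it
    would separate it from everything).
    """
    target = set(nn_ids)
    # postorder tipset accumulation over the (arbitrarily) rooted tree; each
    # non-root node's tipset is one side of its parent edge
    tipsets: dict[int, set[str]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            tipsets[id(node)] = {node.name}
        else:
            tipsets[id(node)] = set().union(*(tipsets[id(c)] for c in node.children))
    for node in tree.postorder(include_self=False):
        side = tipsets[id(node)]
        if sid not in side and target <= side:
            return True
        if sid in side and side != {sid} and not (target & side):
            return True
    return False
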