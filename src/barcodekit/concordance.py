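"""Species/MOTU concordance classification.

Each reference species is compared with a MOTU partition and placed in one
of four mutually exclusive categories:

* **MATCH** — all its specimens form one MOTU containing no other species;
* **SPLIT(k)** — its specimens are divided over k >= 2 MOTUs, none shared
  with another species;
* **MERGE** — all its specimens sit in a single MOTU shared with at least
  one other species;
* **MIXTURE(k)** — the species spans k >= 2 MOTUs and at least one of them
  is shared (it is involved in both a split and a merge).

Singleton species are classifiable (alone in a MOTU = MATCH, in a shared
MOTU = MERGE).  Percentages are computed over the labeled species count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .motu import Partition

__all__ = ["ConcordanceReport", "classify_species", "flag_deep_divergence", "CATEGORIES"]

CATEGORIES = ("MATCH", "SPLIT", "MERGE", "MIXTURE")


@dataclass
class ConcordanceReport:
    """Per-species categories and per-partition percentages."""

    method: str
    per_species: pd.DataFrame  # species, n, category, k, motus_involved
    summary: pd.DataFrame  # category, count, percent

    def percent(self, category: str) -> float:
        row = self.summary[self.summary["category"] == category]
        return float(row["percent"].iloc[0]) if len(row) else 0.0


def classify_species(partition: Partition, labels: Mapping[str, str]) -> ConcordanceReport:
    """Classify every labeled species against a partition."""
    assignment = partition.assignment
    species_of: dict[str, str] = {}
    for sid in assignment:
        sp = labels.get(sid, "") or ""
        if not sp:
            warnings.warn(f"sequence {sid} has no species label; excluded from concordance")
            continue
        species_of[sid] = sp

    missing = [sid for sid, sp in labels.items() if sp and sid not in assignment]
    if missing:
        raise ValueError(f"partition does not cover labeled sequences: {sorted(missing)[:5]}")

    motu_species: dict[int, set[str]] = {}
    species_motus: dict[str, set[int]] = {}
    for sid, sp in species_of.items():
        m = assignment[sid]
        motu_species.setdefault(m, set()).add(sp)
        species_motus.setdefault(sp, set()).add(m)

    rows = []
    for sp in sorted(species_motus):
        motus = species_motus[sp]
        k = len(motus)
        shared = any(len(motu_species[m]) > 1 for m in motus)
        if k == 1 and not shared:
            cat = "MATCH"
        elif k >= 2 and not shared:
            cat = "SPLIT"
        elif k == 1 and shared:
            cat = "MERGE"
        else:
            cat = "MIXTURE"
        n_ind = sum(1 for sid, s in species_of.items() if s == sp)
        rows.append(
            {
                "species": sp,
                "n": n_ind,
                "category": cat,
                "k": k if cat in ("SPLIT", "MIXTURE") else np.nan,
                "motus_involved": sorted(motus),
            }
        )
    per_species = pd.DataFrame(rows, columns=["species", "n", "category", "k", "motus_involved"])

    n_species = len(per_species)
    summary = pd.DataFrame(
        [
            {
                "category": cat,
                "count": int((per_species["category"] == cat).sum()),
                "percent": 100.0 * (per_species["category"] == cat).sum() / n_species
                if n_species
                else np.nan,
            }
            for cat in CATEGORIES
        ]
    )
    return ConcordanceReport(method=partition.method, per_species=per_species, summary=summary)


def flag_deep_divergence(
    dm: DistanceMatrix, labels: Mapping[str, str], cutoff: float
) -> pd.DataFrame:
    """Species whose maximum intraspecific distance reaches ``cutoff``.

    Returns (species, n, max_intraspecific) sorted by decreasing divergence;
    the paper-style screen for candidate cryptic diversity uses the 95th
    percentile of intraspecific distances as the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lab = np.array([labels.get(sid, "") or "" for sid in dm.ids], dtype=object)
    rows = []
    for sp in sorted(set(lab) - {""}):
        members = np.flatnonzero(lab == sp)
        if members.size < 2:
            continue
        sub = dm.d[np.ix_(members, members)]
        iu = np.triu_indices(members.size, k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        if vals.size and vals.max() >= cutoff:
            rows.append({"species": sp, "n": int(members.size), "max_intraspecific": float(vals.max())})
    out = pd.DataFrame(rows, columns=["species", "n", "max_intraspecific"])
    return out.sort_values("max_intraspecific", ascending=False).reset_index(drop=True)
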