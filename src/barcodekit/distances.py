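"""Pairwise sequence divergences under pairwise deletion.

Distances are computed either uncorrected (p-distance, the raw fraction of
differing sites) or with the Kimura 2-parameter correction

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where P and Q are the observed transition (A<->G, C<->T) and transversion
fractions over the sites comparable in both sequences.  *Pairwise deletion*
means a position is dropped for a pair when either sequence carries a gap or
any IUPAC ambiguity there; partial ambiguities (R, Y, ...) are excluded
outright rather than fractionally matched.

Distances are stored as fractions; reports multiply by 100.  A pair whose
K2P logarithm is undefined (saturation) is recorded as missing (NaN), never
silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import BarcodeDataset

__all__ = [
    "DistanceMatrix",
    "SaturatedDistanceWarning",
    "encode_sequences",
    "pairwise_site_classes",
    "k2p_distance",
    "p_distance",
    "distance_matrix",
    "distance_matrix_from_codes",
    "difference_counts",
]

# A=0, G=2 (purines, even); C=1, T=3 (pyrimidines, odd) -> a substitution is a
# transition exactly when both codes share parity.
_CODE = np.full(256, 255, dtype=np.uint8)
for base, code in zip("ACGT", (0, 1, 2, 3)):
    _CODE[ord(base)] = code
    _CODE[ord(base.lower())] = code


class SaturatedDistanceWarning(UserWarning):
    """A pair's K2P distance was inestimable (log argument <= 0 or no sites)."""


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as a (n, L) uint8 matrix; 255 = non-ACGT."""
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned to equal length")
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(len(seqs), L)


def pairwise_site_classes(a: str, b: str) -> tuple[int, float, float]:
    """Comparable-site count n and transition/transversion fractions (P, Q).

    Positions where either sequence is a gap or an ambiguity code are excluded
    (pairwise deletion).  With n = 0 the fractions are returned as 0.0 and the
    caller must treat the distance as inestimable.
    """
    codes = encode_sequences([a, b])
    n, ts, tv = _site_counts(codes[0], codes[1])
    if n == 0:
        return 0, 0.0, 0.0
    return n, ts / n, tv / n


def _site_counts(ca: np.ndarray, cb: np.ndarray) -> tuple[int, int, int]:
    mask = (ca < 4) & (cb < 4)
    diff = (ca != cb) & mask
    ts = int((diff & ((ca & 1) == (cb & 1))).sum())
    tv = int(diff.sum()) - ts
    return int(mask.sum()), ts, tv


def k2p_from_PQ(P: float | np.ndarray, Q: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the K2P formula; NaN where the logs are undefined."""
    with np.errstate(invalid="ignore", divide="ignore"):
        a1 = 1.0 - 2.0 * np.asarray(P, dtype=float) - np.asarray(Q, dtype=float)
        a2 = 1.0 - 2.0 * np.asarray(Q, dtype=float)
        d = np.where(
            (a1 > 0) & (a2 > 0),
            -0.5 * np.log(np.where(a1 > 0, a1, 1.0))
            - 0.25 * np.log(np.where(a2 > 0, a2, 1.0)),
            np.nan,
        )
    d = d + 0.0  # normalize -0.0 from identical pairs
    if np.ndim(d) == 0:
        return float(d)
    return d


def k2p_distance(a: str, b: str) -> float:
    """K2P divergence of two aligned sequences; NaN if inestimable."""
    n, P, Q = pairwise_site_classes(a, b)
    if n == 0:
        warnings.warn("no comparable sites; distance inestimable", SaturatedDistanceWarning)
        return float("nan")
    d = k2p_from_PQ(P, Q)
    if np.isnan(d):
        warnings.warn("saturated pair; K2P inestimable", SaturatedDistanceWarning)
    return d


def p_distance(a: str, b: str) -> float:
    """Uncorrected divergence (fraction of differing comparable sites)."""
    n, P, Q = pairwise_site_classes(a, b)
    if n == 0:
        warnings.warn("no comparable sites; distance inestimable", SaturatedDistanceWarning)
        return float("nan")
    return P + Q


@dataclass
class DistanceMatrix:
    """Symmetric pairwise divergence matrix with provenance.

    ``d`` holds fractions (0.05 = 5%); ``comparable_sites`` the per-pair site
    counts actually used.  Missing (inestimable) pairs are NaN.
    """

    ids: list[str]
    d: np.ndarray
    model: str  # {"p", "K2P"}
    comparable_sites: np.ndarray
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.d) != 0):
            raise ValueError("nonzero diagonal")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        idx = np.array([self._index[i] for i in ids], dtype=int)
        return DistanceMatrix(
            ids=[self.ids[i] for i in idx],
            d=self.d[np.ix_(idx, idx)].copy(),
            model=self.model,
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)].copy(),
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) distances as a flat vector."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    @property
    def n_missing_pairs(self) -> int:
        return int(np.isnan(self.condensed()).sum())

    # -- serialization ---------------------------------------------------------
    def to_square_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    def to_long_tsv(self, path) -> None:
        iu = np.triu_indices(len(self.ids), k=1)
        ids = np.asarray(self.ids)
        pd.DataFrame(
            {
                "id1": ids[iu[0]],
                "id2": ids[iu[1]],
                "model": self.model,
                "distance": self.d[iu],
                "sites": self.comparable_sites[iu],
            }
        ).to_csv(path, sep="\t", index=False)


def _pair_counts_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs comparable-site, transition and transversion counts."""
    n, L = codes.shape
    valid = codes < 4
    parity = codes & 1
    nsites = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        m = valid[i] & valid[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & m
        t = diff & (parity[i] == parity[i + 1 :])
        nsites[i, i + 1 :] = m.sum(axis=1)
        ts[i, i + 1 :] = t.sum(axis=1)
        tv[i, i + 1 :] = diff.sum(axis=1) - ts[i, i + 1 :]
    for arr in (nsites, ts, tv):
        arr += arr.T
    nsites[np.diag_indices(n)] = valid.sum(axis=1)
    return nsites, ts, tv


def distance_matrix_from_codes(
    codes: np.ndarray, ids: Sequence[str], model: str = "K2P"
) -> DistanceMatrix:
    """Distance matrix from an encoded (n, L) alignment; see ``encode_sequences``."""
    if model not in ("p", "K2P"):
        raise ValueError(f"unknown model {model!r}")
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    nsites, ts, tv = _pair_counts_matrix(codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(nsites > 0, ts / np.maximum(nsites, 1), np.nan)
        Q = np.where(nsites > 0, tv / np.maximum(nsites, 1), np.nan)
    if model == "p":
        d = P + Q
    else:
        d = k2p_from_PQ(P, Q)
    np.fill_diagonal(d, 0.0)
    n_bad = int(np.isnan(d[np.triu_indices(n, k=1)]).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} pair(s) inestimable under model {model}; recorded as missing",
            SaturatedDistanceWarning,
        )
    return DistanceMatrix(ids=list(ids), d=d, model=model, comparable_sites=nsites)


def distance_matrix(ds: BarcodeDataset, model: str = "K2P") -> DistanceMatrix:
    """Full pairwise distance matrix for a data set."""
    codes = encode_sequences(ds.sequences())
    return distance_matrix_from_codes(codes, ds.ids, model=model)


def difference_counts(ds: BarcodeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Absolute pairwise difference counts over comparable sites.

    Returns ``(diffs, nsites)`` integer matrices; used by the statistical
    parsimony clusterer, which links haplotypes by mutational steps rather
    than by model-corrected distance.
    """
    codes = encode_sequences(ds.sequences())
    nsites, ts, tv = _pair_counts_matrix(codes)
    return ts + tv, nsites
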