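"""Kimura two-parameter (K2P) pairwise distances with pairwise deletion.

For each pair of aligned sequences, columns where either member carries a
gap, ``?`` or an IUPAC ambiguity code are dropped (pairwise deletion). Over
the remaining ``n`` comparable sites, with transition fraction ``P``
(A<->G, C<->T) and transversion fraction ``Q`` (all other mismatches),

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

The estimator is *undefined* — not an exception — when a log argument is
non-positive (saturation) or no sites are comparable; undefined pairs are
stored as NaN, tracked explicitly, and excluded from every downstream
summary rather than coerced to a large constant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import numpy as np

from .errors import AlignmentError, InsufficientDataError
from .sequence_io import AlignedMarkerSet

# Base codes: A,C,G,T -> 0..3; everything else (gap/missing/ambiguity) -> 4.
# Transitions pair codes of equal parity (A=0,G=2 / C=1,T=3).
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class K2PResult(NamedTuple):
    distance: float | None  # None when the estimator is undefined
    n_compared: int


def encode_sequences(sequences: list[str] | tuple[str, ...]) -> np.ndarray:
    """Pack aligned sequences into an (n_samples, n_sites) uint8 code matrix."""
    joined = "".join(sequences).encode("ascii")
    arr = _CODE[np.frombuffer(joined, dtype=np.uint8)]
    return arr.reshape(len(sequences), -1)


def encode_alignment(ms: AlignedMarkerSet) -> np.ndarray:
    return encode_sequences([r.sequence for r in ms.records])


def k2p_from_counts(n: int, n_ts: int, n_tv: int) -> float | None:
    """Evaluate the K2P formula from site counts; None when undefined."""
    if n == 0:
        return None
    p = n_ts / n
    q = n_tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(a: str, b: str) -> K2PResult:
    """K2P distance between two equal-length aligned sequences."""
    if len(a) != len(b):
        raise AlignmentError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    ca, cb = encode_sequences([a, b])
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    diff = valid & (ca != cb)
    ts = diff & ((ca & 1) == (cb & 1))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return K2PResult(k2p_from_counts(n, n_ts, n_tv), n)


def p_distance(a: str, b: str) -> float | None:
    """Uncorrected proportion of differing comparable sites (pairwise deletion)."""
    ca, cb = encode_sequences([a, b])
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    if n == 0:
        return None
    return int((valid & (ca != cb)).sum()) / n


def k2p_matrix_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs K2P over an encoded alignment.

    Returns (values, n_compared); undefined entries are NaN. Vectorized one
    row against all later rows, which keeps bootstrap replicates cheap.
    """
    n = codes.shape[0]
    values = np.zeros((n, n), dtype=float)
    ncmp = np.zeros((n, n), dtype=np.int64)
    good = codes < 4
    parity = codes & 1
    for i in range(n - 1):
        valid = good[i] & good[i + 1 :]
        cnt = valid.sum(axis=1)
        diff = valid & (codes[i] != codes[i + 1 :])
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            p = ts / cnt
            q = tv / cnt
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            d = np.where(
                (w1 > 0) & (w2 > 0), -0.5 * np.log(np.abs(w1)) - 0.25 * np.log(np.abs(w2)), np.nan
            )
        d = np.where(cnt > 0, d, np.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        ncmp[i, i + 1 :] = cnt
        ncmp[i + 1 :, i] = cnt
    return values, ncmp


@dataclass
class DistanceMatrix:
    """Symmetric K2P distances over samples, with undefined-pair bookkeeping.

    ``values`` holds substitutions/site with NaN marking undefined pairs;
    the diagonal is identically zero.
    """

    sample_ids: tuple[str, ...]
    species_of: Mapping[str, str]
    values: np.ndarray
    n_compared: np.ndarray | None = None
    marker_name: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix is not symmetric")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("negative distance entries")
        np.fill_diagonal(self.values, 0.0)
        self._index = {sid: i for i, sid in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def distance(self, a: str, b: str) -> float:
        """May be NaN for an undefined pair."""
        return float(self.values[self._index[a], self._index[b]])

    @property
    def undefined_pairs(self) -> set[frozenset[str]]:
        out = set()
        ii, jj = np.where(np.isnan(self.values))
        for i, j in zip(ii, jj):
            if i < j:
                out.add(frozenset((self.sample_ids[i], self.sample_ids[j])))
        return out

    def species_indices(self) -> dict[str, list[int]]:
        by_sp: dict[str, list[int]] = {}
        for i, sid in enumerate(self.sample_ids):
            by_sp.setdefault(self.species_of[sid], []).append(i)
        return by_sp

    def iter_pairs(self) -> Iterator[tuple[str, str, float, str]]:
        """Yield (id_a, id_b, distance, 'intra'|'inter') for all unordered pairs."""
        for i, j in itertools.combinations(range(self.n_samples), 2):
            a, b = self.sample_ids[i], self.sample_ids[j]
            kind = "intra" if self.species_of[a] == self.species_of[b] else "inter"
            yield a, b, float(self.values[i, j]), kind

    def intra_distances(self) -> np.ndarray:
        """Defined conspecific pairwise distances, pooled."""
        return np.array(
            [d for _, _, d, k in self.iter_pairs() if k == "intra" and not math.isnan(d)]
        )

    def inter_distances(self) -> np.ndarray:
        """Defined heterospecific pairwise distances, pooled."""
        return np.array(
            [d for _, _, d, k in self.iter_pairs() if k == "inter" and not math.isnan(d)]
        )

    def submatrix(self, sample_ids: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        idx = [self._index[sid] for sid in sample_ids]
        return DistanceMatrix(
            tuple(sample_ids),
            {sid: self.species_of[sid] for sid in sample_ids},
            self.values[np.ix_(idx, idx)].copy(),
            None if self.n_compared is None else self.n_compared[np.ix_(idx, idx)].copy(),
            self.marker_name,
        )

    # --- serialization -----------------------------------------------------

    def to_phylip(self, path: str | Path, nan_token: str = "NA") -> None:
        """PHYLIP square matrix; undefined pairs written as ``nan_token``."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_samples}\n")
            for i, sid in enumerate(self.sample_ids):
                row = " ".join(
                    nan_token if math.isnan(v) else f"{v:.10f}" for v in self.values[i]
                )
                fh.write(f"{sid}  {row}\n")

    def to_long_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_i\tsample_j\tdistance\tn_compared\n")
            for i, j in itertools.combinations(range(self.n_samples), 2):
                d = self.values[i, j]
                nc = 0 if self.n_compared is None else int(self.n_compared[i, j])
                dtxt = "NA" if math.isnan(d) else f"{d:.10f}"
                fh.write(f"{self.sample_ids[i]}\t{self.sample_ids[j]}\t{dtxt}\t{nc}\n")


def read_phylip(path: str | Path, species_of: Mapping[str, str], nan_token: str = "NA") -> DistanceMatrix:
    """Read a PHYLIP square matrix written by :meth:`DistanceMatrix.to_phylip`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([math.nan if tok == nan_token else float(tok) for tok in parts[1:]])
    return DistanceMatrix(tuple(ids), dict(species_of), np.array(rows))


def pairwise_matrix(ms: AlignedMarkerSet) -> DistanceMatrix:
    """K2P distance matrix for every unordered pair in the marker set."""
    if len(ms.records) < 2:
        raise InsufficientDataError("pairwise_matrix needs at least 2 records")
    codes = encode_alignment(ms)
    values, ncmp = k2p_matrix_from_codes(codes)
    return DistanceMatrix(ms.sample_ids, ms.species_of, values, ncmp, ms.marker_name)
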