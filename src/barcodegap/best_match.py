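"""Best Match (BM) and Best Close Match (BCM) identification tests.

Each query sequence is matched against all other sequences in the dataset.
Under BM the query's verdict depends on the species of *all* non-self
samples tied at the minimal defined distance: ``correct`` if every best
match is conspecific, ``incorrect`` if every best match is heterospecific,
``ambiguous`` if mixed. Under BCM a query whose best distance exceeds a
threshold — by convention the 95th percentile of the pooled intraspecific
distance distribution — is ``unidentified``; otherwise the BM rule applies.

Only samples from species with more than one individual are evaluated as
queries; singleton-species samples remain in the reference set as potential
(mis)matches. A tie at the threshold boundary counts as within threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import InsufficientDataError, ThresholdError

logger = logging.getLogger(__name__)

VERDICTS = ("correct", "ambiguous", "incorrect", "unidentified")


@dataclass(frozen=True)
class QueryVerdict:
    sample_id: str
    species: str
    best_match_ids: frozenset[str]
    best_distance: float
    verdict: str


@dataclass(frozen=True)
class IdentificationReport:
    method: str  # "BM" | "BCM"
    threshold: float | None
    verdicts: tuple[QueryVerdict, ...]

    @property
    def n_queries(self) -> int:
        return len(self.verdicts)

    def _pct(self, verdict: str) -> float:
        if not self.verdicts:
            return 0.0
        return 100.0 * sum(1 for v in self.verdicts if v.verdict == verdict) / len(self.verdicts)

    @property
    def pct_correct(self) -> float:
        return self._pct("correct")

    @property
    def pct_ambiguous(self) -> float:
        return self._pct("ambiguous")

    @property
    def pct_incorrect(self) -> float:
        return self._pct("incorrect")

    @property
    def pct_unidentified(self) -> float:
        return self._pct("unidentified")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": v.sample_id,
                    "species": v.species,
                    "best_distance": v.best_distance,
                    "best_match_ids": ",".join(sorted(v.best_match_ids)),
                    "verdict": v.verdict,
                }
                for v in self.verdicts
            ]
        )


def _evaluated_queries(dm: DistanceMatrix) -> list[int]:
    by_sp = dm.species_indices()
    multi = {sp for sp, idx in by_sp.items() if len(idx) >= 2}
    if not multi:
        raise InsufficientDataError("identification tests need >= 1 multi-individual species")
    return [i for i, sid in enumerate(dm.sample_ids) if dm.species_of[sid] in multi]


def _bm_verdict(dm: DistanceMatrix, qi: int) -> QueryVerdict | None:
    row = dm.values[qi].copy()
    row[qi] = math.nan  # never match self
    if np.all(np.isnan(row)):
        logger.warning(
            "query %s has no defined distance to any sample; dropped",
            dm.sample_ids[qi],
        )
        return None
    best = float(np.nanmin(row))
    tied = np.where(row == best)[0]
    ids = frozenset(dm.sample_ids[j] for j in tied)
    q_sp = dm.species_of[dm.sample_ids[qi]]
    species = {dm.species_of[dm.sample_ids[j]] for j in tied}
    if species == {q_sp}:
        verdict = "correct"
    elif q_sp in species:
        verdict = "ambiguous"
    else:
        verdict = "incorrect"
    return QueryVerdict(dm.sample_ids[qi], q_sp, ids, best, verdict)


def best_match_test(dm: DistanceMatrix) -> IdentificationReport:
    """BM verdicts for every query from a multi-individual species."""
    verdicts = []
    for qi in _evaluated_queries(dm):
        v = _bm_verdict(dm, qi)
        if v is not None:
            verdicts.append(v)
    return IdentificationReport("BM", None, tuple(verdicts))


def bcm_threshold(dm: DistanceMatrix, percentile: float = 95.0) -> float:
    """Percentile of the pooled intraspecific distance distribution.

    Linear interpolation between order statistics (numpy's default rule).
    """
    intra = dm.intra_distances()
    if intra.size == 0:
        raise ThresholdError("no defined intraspecific pair distances")
    return float(np.percentile(intra, percentile))


def best_close_match_test(dm: DistanceMatrix, threshold: float) -> IdentificationReport:
    """BCM verdicts: BM verdicts for queries within the threshold, else unidentified."""
    verdicts = []
    for qi in _evaluated_queries(dm):
        v = _bm_verdict(dm, qi)
        if v is None:
            continue
        if v.best_distance > threshold:
            v = QueryVerdict(v.sample_id, v.species, frozenset(), v.best_distance, "unidentified")
        verdicts.append(v)
    return IdentificationReport("BCM", threshold, tuple(verdicts))


def summary_frame(reports: list[IdentificationReport]) -> pd.DataFrame:
    """Summary table: one row per report, identification-success column schema."""
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "threshold": r.threshold,
                "n_queries": r.n_queries,
                "pct_correct": r.pct_correct,
                "pct_ambiguous": r.pct_ambiguous,
                "pct_incorrect": r.pct_incorrect,
                "pct_unidentified": r.pct_unidentified,
            }
            for r in reports
        ]
    )
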