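"""End-to-end evaluation of markers and marker combinations.

For every single marker and every declared combination, the pipeline
computes the full report surface: alignment site statistics and the six
divergence parameters (the marker-characteristics table), the barcoding-gap
assessment, BM/BCM identification reports (the identification-success
table), and the NJ bootstrap tree with per-species monophyly verdicts.
A cross-method resolution matrix collates the three discrimination rates,
always alongside their numerator/denominator pairs.

All randomness flows from one seed; per-unit bootstrap seeds are derived
deterministically from it, so a rerun with the same config and seed yields
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .best_match import (
    IdentificationReport,
    bcm_threshold,
    best_close_match_test,
    best_match_test,
    summary_frame,
)
from .distances import DistanceMatrix, pairwise_matrix
from .divergence_stats import DivergenceSummary, divergence_summary
from .errors import ConfigError
from .gap_analysis import GapAssessment, assess_gap, histogram_frame
from .sequence_io import (
    AlignedMarkerSet,
    SiteSummary,
    concatenate,
    read_aligned_fasta,
    site_summary,
    write_boundary_table,
)
from .tree_eval import MonophylyResult, Phylogeny, assess_monophyly, bootstrap_supports

logger = logging.getLogger(__name__)


@dataclass
class EvaluationConfig:
    markers: dict[str, Path]  # marker name -> aligned FASTA path
    combinations: tuple[tuple[str, ...], ...] = ()
    outgroup: tuple[str, ...] = ()  # sample ids used to root trees
    n_bootstrap: int = 1000
    support_threshold: float = 0.70
    bcm_percentile: float = 95.0
    bin_width: float = 0.005
    concat_policy: str = "complete_case"
    seed: int = 0
    header_delimiter: str = "|"

    def validate(self) -> None:
        for combo in self.combinations:
            unknown = [m for m in combo if m not in self.markers]
            if unknown:
                raise ConfigError(f"combination {combo} references undeclared markers {unknown}")
            if len(combo) < 2:
                raise ConfigError(f"combination {combo} needs >= 2 markers")

    def to_dict(self) -> dict:
        return {
            "markers": {k: str(v) for k, v in self.markers.items()},
            "combinations": [list(c) for c in self.combinations],
            "outgroup": list(self.outgroup),
            "n_bootstrap": self.n_bootstrap,
            "support_threshold": self.support_threshold,
            "bcm_percentile": self.bcm_percentile,
            "bin_width": self.bin_width,
            "concat_policy": self.concat_policy,
            "seed": self.seed,
            "header_delimiter": self.header_delimiter,
        }


@dataclass
class UnitResult:
    """All report surfaces for one marker or combination."""

    name: str
    marker_set: AlignedMarkerSet
    sites: SiteSummary
    divergence: DivergenceSummary
    gap: GapAssessment
    bm: IdentificationReport
    bcm: IdentificationReport
    phylogeny: Phylogeny | None
    monophyly: MonophylyResult | None


@dataclass
class EvaluationBundle:
    config: EvaluationConfig
    units: dict[str, UnitResult]
    failures: dict[str, str] = field(default_factory=dict)


def unit_seed(master_seed: int, unit_name: str) -> int:
    """Stable per-unit bootstrap seed below 2**31."""
    return (master_seed * 1000003 + zlib.crc32(unit_name.encode())) % (2**31)


def evaluate_unit(
    name: str, ms: AlignedMarkerSet, cfg: EvaluationConfig
) -> UnitResult:
    dm = pairwise_matrix(ms)
    if dm.undefined_pairs:
        logger.warning("%s: %d undefined (saturated/incomparable) pairs excluded",
                       name, len(dm.undefined_pairs))
    outgroup = tuple(s for s in cfg.outgroup if s in ms.sample_ids)
    og_species = {ms.species_of[s] for s in outgroup}
    ingroup_ids = [s for s in ms.sample_ids if ms.species_of[s] not in og_species]
    dm_in = dm.submatrix(ingroup_ids) if outgroup else dm

    sites = site_summary(ms)
    divergence = divergence_summary(dm_in)
    gap = assess_gap(dm_in, cfg.bin_width)
    bm = best_match_test(dm_in)
    bcm = best_close_match_test(dm_in, bcm_threshold(dm_in, cfg.bcm_percentile))

    phylogeny = monophyly = None
    if cfg.n_bootstrap > 0 and len(ms.records) >= 3:
        phylogeny = bootstrap_supports(
            ms, cfg.n_bootstrap, unit_seed(cfg.seed, name), outgroup or None
        )
        monophyly = assess_monophyly(phylogeny, dict(ms.species_of), cfg.support_threshold)
    return UnitResult(name, ms, sites, divergence, gap, bm, bcm, phylogeny, monophyly)


def evaluate_all(cfg: EvaluationConfig) -> EvaluationBundle:
    """Evaluate every declared marker and combination; failures are isolated."""
    cfg.validate()
    marker_sets = {
        name: read_aligned_fasta(path, cfg.header_delimiter, marker_name=name)
        for name, path in cfg.markers.items()
    }
    units: dict[str, UnitResult] = {}
    failures: dict[str, str] = {}
    jobs: list[tuple[str, AlignedMarkerSet]] = list(marker_sets.items())
    for combo in cfg.combinations:
        name = "+".join(combo)
        try:
            jobs.append((name, concatenate([marker_sets[m] for m in combo], cfg.concat_policy, name)))
        except Exception as exc:  # pragma: no cover - combination construction failure
            failures[name] = str(exc)
            logger.error("combination %s failed: %s", name, exc)
    for name, ms in jobs:
        try:
            units[name] = evaluate_unit(name, ms, cfg)
        except Exception as exc:
            failures[name] = str(exc)
            logger.error("unit %s failed: %s", name, exc)
    return EvaluationBundle(cfg, units, failures)


# --- report rendering ------------------------------------------------------


def marker_table(bundle: EvaluationBundle) -> pd.DataFrame:
    """Marker-characteristics table: one column per unit (Table-1-style schema)."""
    rows = {
        "Aligned length (bp)": lambda u: u.marker_set.aligned_length,
        "Average intra-distance (%)": lambda u: u.divergence.avg_intra,
        "Average inter-distance (%)": lambda u: u.divergence.avg_inter,
        "Average theta (%)": lambda u: u.divergence.theta,
        "Coalescent depth (%)": lambda u: u.divergence.coalescent_depth,
        "Average theta prime (%)": lambda u: u.divergence.theta_prime,
        "Smallest inter-distance (%)": lambda u: u.divergence.smallest_inter,
        "Proportion of variable sites (%)": lambda u: 100.0 * u.sites.prop_variable,
        "Proportion of parsimony sites (%)": lambda u: 100.0 * u.sites.prop_parsimony,
    }
    data = {
        name: [fn(unit) for fn in rows.values()] for name, unit in bundle.units.items()
    }
    return pd.DataFrame(data, index=list(rows))


def identification_table(bundle: EvaluationBundle) -> pd.DataFrame:
    """BM/BCM identification-success table (Table-2-style schema)."""
    rows = []
    for name, unit in bundle.units.items():
        for rep in (unit.bm, unit.bcm):
            rows.append(
                {
                    "unit": name,
                    "method": rep.method,
                    "n_queries": rep.n_queries,
                    "pct_correct": rep.pct_correct,
                    "pct_ambiguous": rep.pct_ambiguous,
                    "pct_incorrect": rep.pct_incorrect,
                    "pct_unidentified": rep.pct_unidentified,
                }
            )
    return pd.DataFrame(rows)


def resolution_matrix(bundle: EvaluationBundle) -> pd.DataFrame:
    """Cross-method discrimination rates with numerators/denominators."""
    rows = []
    for name, unit in bundle.units.items():
        local = unit.gap.local
        n_gap = sum(1 for g in local.per_species.values() if g.gap)
        row = {
            "unit": name,
            "local_gap_rate": 100.0 * local.resolution_rate,
            "local_gap_n": n_gap,
            "local_gap_N": local.n_evaluated,
            "bm_correct_rate": unit.bm.pct_correct,
            "bm_n": sum(1 for v in unit.bm.verdicts if v.verdict == "correct"),
            "bm_N": unit.bm.n_queries,
            "bcm_correct_rate": unit.bcm.pct_correct,
            "bcm_n": sum(1 for v in unit.bcm.verdicts if v.verdict == "correct"),
            "bcm_N": unit.bcm.n_queries,
        }
        if unit.monophyly is not None:
            n_sup = sum(
                1 for v in unit.monophyly.verdicts if v.status == "supported_monophyletic"
            )
            row.update(
                monophyly_rate=100.0 * unit.monophyly.resolution_rate,
                monophyly_n=n_sup,
                monophyly_N=unit.monophyly.n_evaluated,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def render_rounded(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Percentages rounded to 2 decimals for display; machine output stays full."""
    return df.round(decimals)


def write_bundle(bundle: EvaluationBundle, outdir: str | Path) -> None:
    """Write all machine-precision and rendered report files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    marker_table(bundle).to_csv(outdir / "marker_table.tsv", sep="\t", float_format=fmt)
    render_rounded(marker_table(bundle)).to_csv(outdir / "marker_table_rendered.tsv", sep="\t")
    identification_table(bundle).to_csv(
        outdir / "identification_table.tsv", sep="\t", index=False, float_format=fmt
    )
    resolution_matrix(bundle).to_csv(
        outdir / "resolution_matrix.tsv", sep="\t", index=False, float_format=fmt
    )
    for name, unit in bundle.units.items():
        udir = outdir / "units" / name.replace("+", "_")
        udir.mkdir(parents=True, exist_ok=True)
        unit.gap.local.to_frame().to_csv(
            udir / "local_gap.tsv", sep="\t", index=False, float_format=fmt
        )
        histogram_frame(unit.gap.distributions).to_csv(
            udir / "distance_histogram.csv", index=False, float_format=fmt
        )
        unit.bm.to_frame().to_csv(udir / "bm_verdicts.tsv", sep="\t", index=False, float_format=fmt)
        unit.bcm.to_frame().to_csv(udir / "bcm_verdicts.tsv", sep="\t", index=False, float_format=fmt)
        summary_frame([unit.bm, unit.bcm]).to_csv(
            udir / "identification_summary.tsv", sep="\t", index=False, float_format=fmt
        )
        if unit.marker_set.boundaries:
            write_boundary_table(unit.marker_set, udir / "marker_boundaries.tsv")
        if unit.phylogeny is not None:
            unit.phylogeny.write_newick(udir / "nj_bootstrap.nwk")
        if unit.monophyly is not None:
            unit.monophyly.to_frame().to_csv(
                udir / "monophyly.tsv", sep="\t", index=False, float_format=fmt
            )
    cfg_json = json.dumps(bundle.config.to_dict(), sort_keys=True)
    manifest = {
        "package": "barcodegap",
        "version": __version__,
        "seed": bundle.config.seed,
        "config": bundle.config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "units": sorted(bundle.units),
        "failures": bundle.failures,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
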