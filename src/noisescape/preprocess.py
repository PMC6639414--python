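"""Promoter and gene quality control.

Implements the pre-processing applied before landscape reconstruction:
cross-platform calibration of mean-expression estimates (plasmid vs
genomic-locus reporter), exclusion of promoters with discordant estimates
(> 0.5 log2 units) or noisy fitness (median error > 0.1), restriction to
the homogenously populated expression window [2, 6] log2 units, selection
of genes whose wild-type expression sits in the centre of that window
([3, 5]), loess smoothing of replicate-derived expression errors, and
removal of strains whose promoter contains a predicted binding motif for
the driven gene (supplied as an explicit exclusion list).

All window boundaries are inclusive; filters are idempotent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

CALIBRATION_OUTLIER_LOG2 = 0.5
FITNESS_ERROR_THRESHOLD = 0.1
EXPRESSION_WINDOW = (2.0, 6.0)
GENE_WINDOW = (3.0, 5.0)


@dataclass
class QcReport:
    """Per-promoter and per-gene QC flags plus calibration coefficients.

    Each promoter (gene) appears exactly once in ``promoter_flags``
    (``gene_flags``); ``rule`` names the first filter that failed, or
    ``"pass"``.
    """

    promoter_flags: dict[str, str] = field(default_factory=dict)
    gene_flags: dict[str, str] = field(default_factory=dict)
    calibration: dict[str, float] = field(default_factory=dict)

    def n_pass(self) -> int:
        return sum(1 for v in self.promoter_flags.values() if v == "pass")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QcReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def calibrate_platforms(plasmid_mu, locus_mu
                        ) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Put plasmid-derived mean expression on the locus scale.

    Degree-1 least squares ``locus ~ a*plasmid + b`` fitted on all paired
    promoters; returns the transformed plasmid values, a boolean outlier
    flag for promoters deviating by more than 0.5 log2 units after the
    transform, and the coefficients (a, b).
    """
    plasmid = np.asarray(plasmid_mu, dtype=float)
    locus = np.asarray(locus_mu, dtype=float)
    if len(plasmid) != len(locus):
        raise ValueError("paired vectors required")
    if len(plasmid) < 2:
        raise ValueError("need >= 2 paired promoters for the calibration fit")
    if np.ptp(plasmid) == 0:
        raise ValueError("degenerate calibration fit: no variance")
    a, b = np.polyfit(plasmid, locus, 1)
    transformed = a * plasmid + b
    outliers = np.abs(transformed - locus) > CALIBRATION_OUTLIER_LOG2
    return transformed, outliers, (float(a), float(b))


def filter_fitness_error(strain_fitness: pd.DataFrame,
                         threshold: float = FITNESS_ERROR_THRESHOLD
                         ) -> pd.Series:
    """Promoters whose median fitness error across genes exceeds threshold.

    Returns a boolean Series indexed by promoter_id, True = excluded.
    The comparison is strict (median exactly at the threshold is retained).
    """
    med = strain_fitness.groupby("promoter_id")["sigma_f"].median()
    return med > threshold


def filter_expression_window(panel: pd.DataFrame,
                             low: float = EXPRESSION_WINDOW[0],
                             high: float = EXPRESSION_WINDOW[1]
                             ) -> pd.DataFrame:
    """Retain promoters with calibrated mean expression in [low, high]."""
    mu = panel["log2_mean"].to_numpy(dtype=float)
    return panel[(mu >= low) & (mu <= high)].copy()


def select_genes(wt_mu: pd.Series | dict,
                 low: float = GENE_WINDOW[0],
                 high: float = GENE_WINDOW[1]) -> list[str]:
    """Genes whose wild-type promoter expression lies in [low, high]."""
    if isinstance(wt_mu, dict):
        wt_mu = pd.Series(wt_mu)
    keep = wt_mu[(wt_mu >= low) & (wt_mu <= high)]
    return list(keep.index)


def estimate_expression_errors(replicate_sd, read_error,
                               span: float = 0.5) -> np.ndarray:
    """Smoothed expression errors from replicate scatter.

    Local (tricube-weighted, linear) regression of the replicate standard
    deviation against the sequencing-read-based error estimate, evaluated
    at each promoter and clipped at zero.
    """
    rep = np.asarray(replicate_sd, dtype=float)
    err = np.asarray(read_error, dtype=float)
    if len(rep) != len(err):
        raise ValueError("paired vectors required")
    if len(rep) < 10:
        raise ValueError("need >= 10 promoters for the loess error model")
    smoothed = lowess(rep, err, frac=span, it=0, return_sorted=False)
    return np.clip(smoothed, 0.0, None)


def exclude_motif_strains(strains: pd.DataFrame,
                          exclusions: list[tuple[str, str]]) -> pd.DataFrame:
    """Drop (promoter, gene) strains with predicted binding motifs.

    The exclusion list comes from configuration; pairs absent from the
    table trigger a warning but no removal.
    """
    if not exclusions:
        return strains.copy()
    keys = set(zip(strains["promoter_id"], strains["gene"]))
    missing = [p for p in exclusions if tuple(p) not in keys]
    if missing:
        warnings.warn(f"{len(missing)} motif exclusion(s) not present in the "
                      f"strain table: {missing}")
    excl = {tuple(p) for p in exclusions}
    mask = [
        (p, g) not in excl
        for p, g in zip(strains["promoter_id"], strains["gene"])
    ]
    return strains[np.asarray(mask)].copy()


def qc_panel(panel: pd.DataFrame, strain_fitness: pd.DataFrame,
             wt_mu: dict[str, float] | pd.Series,
             locus_mu: pd.Series | None = None,
             fitness_error_threshold: float = FITNESS_ERROR_THRESHOLD,
             expression_window: tuple[float, float] = EXPRESSION_WINDOW,
             gene_window: tuple[float, float] = GENE_WINDOW,
             motif_exclusions: list[tuple[str, str]] | None = None,
             ) -> tuple[pd.DataFrame, pd.DataFrame, QcReport]:
    """Run the full promoter/gene QC cascade.

    Applies, in order: platform calibration (when ``locus_mu`` gives a
    second, locus-derived mean-expression estimate per promoter), the
    fitness-error filter, the expression window, gene selection, and motif
    exclusions. Returns the retained panel, the filtered strain table and a
    :class:`QcReport` in which each input promoter and gene appears once.
    """
    report = QcReport()
    panel = panel.copy()

    flags = {p: "pass" for p in panel["promoter_id"]}
    if locus_mu is not None:
        aligned = pd.Series(locus_mu).reindex(panel["promoter_id"]).to_numpy()
        transformed, outliers, (a, b) = calibrate_platforms(
            panel["log2_mean"].to_numpy(), aligned)
        panel["log2_mean"] = transformed
        report.calibration = {"slope": a, "intercept": b}
        for p, bad in zip(panel["promoter_id"], outliers):
            if bad:
                flags[p] = "platform_deviation"

    noisy = filter_fitness_error(strain_fitness, fitness_error_threshold)
    for p, bad in noisy.items():
        if bad and flags.get(p) == "pass":
            flags[p] = "fitness_error"

    lo, hi = expression_window
    mu = panel.set_index("promoter_id")["log2_mean"]
    for p in panel["promoter_id"]:
        if flags[p] == "pass" and not (lo <= mu[p] <= hi):
            flags[p] = "expression_window"

    report.promoter_flags = flags
    retained = panel[[flags[p] == "pass" for p in panel["promoter_id"]]]

    genes = pd.Series(wt_mu)
    selected = set(select_genes(genes, *gene_window))
    report.gene_flags = {g: ("pass" if g in selected else "gene_window")
                         for g in genes.index}

    strains = strain_fitness[
        strain_fitness["promoter_id"].isin(retained["promoter_id"])
        & strain_fitness["gene"].isin(selected)]
    strains = exclude_motif_strains(strains, motif_exclusions or [])
    return retained.reset_index(drop=True), strains.reset_index(drop=True), report
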