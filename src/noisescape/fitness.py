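"""Per-strain relative fitness from pooled-competition read counts.

Fitness of strain i at a later timepoint t is the log2 change of its read
frequency relative to the wild-type lineage,

    f_i_t = log2( (n_i_t / n_wt_t) / (n_i_t0 / n_wt_t0) )

with every count incremented by a pseudo count of 0.1 (which also guards
the count-based error estimate

    sigma_i_t = sqrt(1/n_i_t0 + 1/n_i_t + 1/n_wt_t0 + 1/n_wt_t)

against zeros). The two timepoints (23 h and 35 h) are put on a common
scale by a first-order linear fit across all strains, combined as a
weighted average with weights 1/sigma (verbatim; inverse-variance weighting
is available via ``weights="inverse_var"``), and the combined error is the
inverse-variance combination sigma = (s23^-2 + s35^-2)^(-1/2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PSEUDO_COUNT = 0.1
WILDTYPE_GENE = "WT"

_TP_COLUMNS = {"t0": "t0_reads", "t23": "t23_reads", "t35": "t35_reads"}

FITNESS_COLUMNS = ["strain_id", "promoter_id", "gene", "fitness", "sigma_f",
                   "f23", "f35", "sigma23", "sigma35"]


def _wildtype_row(counts: pd.DataFrame) -> pd.Series:
    wt = counts[counts["gene"] == WILDTYPE_GENE]
    if len(wt) != 1:
        raise ValueError(
            f"expected exactly one wild-type row (gene == {WILDTYPE_GENE!r}),"
            f" found {len(wt)}")
    return wt.iloc[0]


def _col(t) -> str:
    key = t if isinstance(t, str) else f"t{int(t)}"
    if key not in _TP_COLUMNS:
        raise ValueError(f"unknown timepoint {t!r}; use 't23' or 't35'")
    return _TP_COLUMNS[key]


def timepoint_fitness(counts: pd.DataFrame, t) -> pd.Series:
    """log2 frequency change relative to wild type at timepoint ``t``."""
    wt = _wildtype_row(counts)
    n_t = counts[_col(t)].to_numpy(dtype=float) + PSEUDO_COUNT
    n_0 = counts[_TP_COLUMNS["t0"]].to_numpy(dtype=float) + PSEUDO_COUNT
    wt_t = float(wt[_col(t)]) + PSEUDO_COUNT
    wt_0 = float(wt[_TP_COLUMNS["t0"]]) + PSEUDO_COUNT
    f = np.log2((n_t / wt_t) / (n_0 / wt_0))
    return pd.Series(f, index=counts.index, name=f"f_{t}")


def timepoint_error(counts: pd.DataFrame, t) -> pd.Series:
    """Count-based error estimate at timepoint ``t`` (pseudo-counted)."""
    wt = _wildtype_row(counts)
    n_t = counts[_col(t)].to_numpy(dtype=float) + PSEUDO_COUNT
    n_0 = counts[_TP_COLUMNS["t0"]].to_numpy(dtype=float) + PSEUDO_COUNT
    wt_t = float(wt[_col(t)]) + PSEUDO_COUNT
    wt_0 = float(wt[_TP_COLUMNS["t0"]]) + PSEUDO_COUNT
    s = np.sqrt(1.0 / n_0 + 1.0 / n_t + 1.0 / wt_0 + 1.0 / wt_t)
    return pd.Series(s, index=counts.index, name=f"sigma_{t}")


def normalize_timepoints(f23, f35) -> tuple[np.ndarray, tuple[float, float]]:
    """Map 35 h fitness onto the 23 h scale.

    Least-squares fit f23 ~ a*f35 + b across all strains; returns the
    corrected values a*f35 + b and the coefficients (a, b). Raises on a
    degenerate fit (no variance in f35).
    """
    f23 = np.asarray(f23, dtype=float)
    f35 = np.asarray(f35, dtype=float)
    ok = np.isfinite(f23) & np.isfinite(f35)
    if ok.sum() < 3:
        raise ValueError("need >= 3 strains with finite fitness at both "
                         "timepoints")
    if np.ptp(f35[ok]) == 0:
        raise ValueError("degenerate normalization fit: f35 has no variance")
    a, b = np.polyfit(f35[ok], f23[ok], 1)
    return a * f35 + b, (float(a), float(b))


def combine_timepoints(f23, f35corr, sigma23, sigma35,
                       weights: str = "inverse_sd"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted average of the two timepoints and combined error.

    ``weights="inverse_sd"`` averages with weights 1/sigma (as stated);
    ``"inverse_var"`` uses 1/sigma^2. The combined error is always the
    inverse-variance combination.
    """
    f23, f35corr, s23, s35 = (np.asarray(v, dtype=float)
                              for v in (f23, f35corr, sigma23, sigma35))
    if np.any(s23 <= 0) or np.any(s35 <= 0):
        raise ValueError("timepoint errors must be > 0")
    if weights == "inverse_sd":
        w23, w35 = 1.0 / s23, 1.0 / s35
    elif weights == "inverse_var":
        w23, w35 = 1.0 / s23 ** 2, 1.0 / s35 ** 2
    else:
        raise ValueError("weights must be 'inverse_sd' or 'inverse_var'")
    f = (f23 * w23 + f35corr * w35) / (w23 + w35)
    sigma = (s23 ** -2 + s35 ** -2) ** -0.5
    return f, sigma


def strain_fitness_table(counts: pd.DataFrame,
                         weights: str = "inverse_sd") -> pd.DataFrame:
    """Full fitness pipeline on a read-count table.

    Returns one row per strain (wild type included, with fitness exactly 0)
    with combined and per-timepoint fitness and errors. The normalization
    coefficients (a, b) mapping the 35 h scale onto 23 h are stored in
    ``result.attrs["normalization"]``.
    """
    f23 = timepoint_fitness(counts, "t23").to_numpy()
    f35 = timepoint_fitness(counts, "t35").to_numpy()
    s23 = timepoint_error(counts, "t23").to_numpy()
    s35 = timepoint_error(counts, "t35").to_numpy()
    f35c, coeff = normalize_timepoints(f23, f35)
    f, sigma = combine_timepoints(f23, f35c, s23, s35, weights=weights)
    out = pd.DataFrame({
        "strain_id": counts["strain_id"].to_numpy(),
        "promoter_id": counts["promoter_id"].to_numpy(),
        "gene": counts["gene"].to_numpy(),
        "fitness": f, "sigma_f": sigma,
        "f23": f23, "f35": f35c, "sigma23": s23, "sigma35": s35,
    })
    out.attrs["normalization"] = {"a": coeff[0], "b": coeff[1],
                                  "direction": "35h_onto_23h"}
    return out


def write_fitness(table: pd.DataFrame, path) -> None:
    table[FITNESS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fitness(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
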