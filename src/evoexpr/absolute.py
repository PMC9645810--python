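"""Absolute mRNA quantification: spike-in calibration, molecules per CFU,
cell volumes, and total-mRNA-vs-volume scaling.

Synthetic RNA spike-ins added in known molecule counts give, per sample, a
log10-log10 linear calibration between molecules added and observed TPM.
Inverting that calibration converts any gene's TPM into molecules in the
library; dividing by the colony-forming-unit (CFU) count of the culture,
corrected by the sampling fractions of each library-preparation step,
yields mRNA molecules per cell. Cell volumes assume the rod-shaped
spherocylinder geometry of *E. coli*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationFit",
    "AbsoluteAbundance",
    "spherocylinder_volume",
    "cell_volumes",
    "fit_spikein_calibration",
    "tpm_to_molecules",
    "molecules_per_cfu",
    "absolute_fold_changes",
    "total_mrna_vs_volume",
]


@dataclass
class CalibrationFit:
    """OLS fit of log10(TPM) on log10(molecules added) for one sample."""

    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_zero_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_used < 3:
            raise ValueError("calibration needs at least 3 usable spike-ins")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 out of [0, 1]")


@dataclass
class AbsoluteAbundance:
    """Per-gene mRNA molecules per CFU for one sample."""

    sample_id: str
    molecules_per_cfu: pd.Series
    effective_cfu: float
    n_zero_flagged: int = 0

    def __post_init__(self) -> None:
        if self.effective_cfu <= 0:
            raise ValueError("effective CFU must be positive")
        if (self.molecules_per_cfu < 0).any():
            raise ValueError("molecules per CFU must be non-negative")


def spherocylinder_volume(length, width):
    """Volume (um^3) of a spherocylinder: a cylinder of length l - w capped
    by two hemispheres of diameter w.

    V = pi (w/2)^2 (l - w) + (4/3) pi (w/2)^3.  At l == w this degenerates
    to a sphere. Accepts scalars or aligned arrays.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0):
        raise ValueError("width must be positive")
    if np.any(length < width):
        raise ValueError("length must be >= width (rod geometry)")
    r = width / 2.0
    v = np.pi * r**2 * (length - width) + (4.0 / 3.0) * np.pi * r**3
    return v if v.ndim else float(v)


def cell_volumes(geometry: pd.DataFrame) -> pd.DataFrame:
    """Add spherocylinder volumes and per-line medians to a geometry table.

    Expects columns ``line``, ``length_um``, ``width_um``; returns a copy
    with ``volume_um3`` plus a ``median_volume_um3`` per line (broadcast).
    """
    out = geometry.copy()
    out["volume_um3"] = spherocylinder_volume(out["length_um"].to_numpy(), out["width_um"].to_numpy())
    out["median_volume_um3"] = out.groupby("line")["volume_um3"].transform("median")
    return out


def fit_spikein_calibration(
    tpm: AbundanceMatrix | pd.DataFrame, design: pd.DataFrame, sample_id: str
) -> CalibrationFit:
    """OLS of log10(TPM) on log10(molecules added) for one sample's spike-ins.

    ``design`` has columns ``spikein_id``, ``sample_id``, ``molecules``.
    Spike-ins with zero observed TPM cannot enter a log-scale fit; they are
    excluded and counted.
    """
    mat = tpm.tpm if isinstance(tpm, AbundanceMatrix) else tpm
    sub = design[design["sample_id"] == sample_id]
    if (sub["molecules"] <= 0).any():
        raise ValueError("spike-in molecule counts must be positive")
    obs = mat.loc[sub["spikein_id"], sample_id].to_numpy(dtype=float)
    mol = sub["molecules"].to_numpy(dtype=float)
    usable = obs > 0
    n_zero = int((~usable).sum())
    if n_zero:
        logger.info("sample %s: %d spike-ins with zero TPM excluded from calibration", sample_id, n_zero)
    if usable.sum() < 3:
        raise ValueError(f"sample {sample_id}: fewer than 3 spike-ins with positive TPM")
    x = np.log10(mol[usable])
    y = np.log10(obs[usable])
    if np.ptp(x) == 0:
        raise ValueError("spike-in molecule counts are constant; slope undefined")
    fit = stats.linregress(x, y)
    return CalibrationFit(sample_id, float(fit.slope), float(fit.intercept), float(fit.rvalue**2), int(usable.sum()), n_zero)


def tpm_to_molecules(tpm_values: pd.Series, fit: CalibrationFit) -> pd.Series:
    """Invert the calibration: molecules = 10^((log10 TPM - intercept)/slope).

    TPM = 0 has no log-scale preimage and maps to 0 molecules (flagged in
    the log); a non-positive slope means a non-physical calibration.
    """
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    vals = np.asarray(tpm_values, dtype=float)
    if (vals < 0).any():
        raise ValueError("TPM values must be non-negative")
    out = np.zeros_like(vals)
    pos = vals > 0
    out[pos] = 10.0 ** ((np.log10(vals[pos]) - fit.intercept) / fit.slope)
    n_zero = int((~pos).sum())
    if n_zero:
        logger.info("%d genes with TPM=0 mapped to 0 molecules", n_zero)
    return pd.Series(out, index=tpm_values.index)


def molecules_per_cfu(
    molecules: pd.Series,
    cfu_count: float,
    sampling_fractions=(),
    sample_id: str = "",
) -> AbsoluteAbundance:
    """Molecules per CFU with sampling-fraction accounting.

    Each library-preparation step keeps only a fraction of the material; the
    effective cell count is cfu_count times the product of the fractions.
    An empty fraction list means the whole culture was used.
    """
    if cfu_count <= 0:
        raise ValueError("CFU count must be positive")
    fractions = np.asarray(list(sampling_fractions), dtype=float)
    if ((fractions <= 0) | (fractions > 1)).any():
        raise ValueError("sampling fractions must lie in (0, 1]")
    effective = float(cfu_count * np.prod(fractions)) if fractions.size else float(cfu_count)
    return AbsoluteAbundance(sample_id, molecules / effective, effective)


def absolute_fold_changes(
    evolved: list[AbsoluteAbundance], ancestors: list[AbsoluteAbundance]
) -> dict:
    """Per-gene absolute fold-changes with a replicate-null comparison.

    FC_g = mean over evolved replicates / mean over ancestor samples of
    molecules per CFU. The replicate null is the per-gene ratio
    replicate1/replicate2 within the evolved line (first two replicates in
    the given order), which is centered at 1 when replicates are
    exchangeable. A two-sample KS test compares |log2| of the two
    distributions.
    """
    if len(evolved) < 2:
        raise ValueError("need at least 2 evolved replicates")
    if len(ancestors) < 2:
        raise ValueError("need at least 2 ancestor samples")
    ev = pd.concat([a.molecules_per_cfu for a in evolved], axis=1)
    an = pd.concat([a.molecules_per_cfu for a in ancestors], axis=1)
    genes = ev.index.intersection(an.index)
    if len(genes) == 0:
        raise ValueError("no overlapping genes between evolved and ancestor samples")
    ev, an = ev.loc[genes], an.loc[genes]
    anc_mean = an.mean(axis=1)
    nonzero = anc_mean > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("%d genes with zero ancestor mean excluded from fold-changes", n_excluded)
    fc = ev.mean(axis=1)[nonzero] / anc_mean[nonzero]
    rep = ev.iloc[:, 0], ev.iloc[:, 1]
    ok = (rep[1] > 0) & (rep[0] > 0)
    rep_null = (rep[0][ok] / rep[1][ok]).rename("replicate_ratio")
    both = fc[fc > 0]
    ks = stats.ks_2samp(np.abs(np.log2(both)), np.abs(np.log2(rep_null)))
    return {
        "fold_change": fc,
        "replicate_null": rep_null,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_excluded_zero_ancestor": n_excluded,
    }


def total_mrna_vs_volume(totals: pd.Series, median_volumes: pd.Series) -> dict:
    """Association between per-line total mRNA per CFU and median cell volume.

    ``totals`` is the per-line sum over genes of replicate-mean molecules
    per CFU; returns the Pearson correlation and the OLS slope/intercept of
    total on volume across lines.
    """
    lines = totals.index.intersection(median_volumes.index)
    if len(lines) < 3:
        raise ValueError("need at least 3 lines for a stable association")
    x = median_volumes.loc[lines].to_numpy(dtype=float)
    y = totals.loc[lines].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if np.std(y) == 0:
        pearson_r = float("nan")
    else:
        pearson_r = float(stats.pearsonr(x, y)[0])
    return {
        "lines": list(lines),
        "pearson_r": pearson_r,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pvalue": float(fit.pvalue),
    }


def line_totals(per_sample: dict[str, AbsoluteAbundance], sample_to_line: dict[str, str]) -> pd.Series:
    """Per-line total molecules per CFU: sum over genes of the mean across
    that line's replicate samples."""
    by_line: dict[str, list[pd.Series]] = {}
    for sid, ab in per_sample.items():
        by_line.setdefault(sample_to_line[sid], []).append(ab.molecules_per_cfu)
    totals = {ln: float(pd.concat(cols, axis=1).mean(axis=1).sum()) for ln, cols in by_line.items()}
    return pd.Series(totals, name="total_molecules_per_cfu")
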