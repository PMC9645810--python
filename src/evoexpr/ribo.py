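"""Codon-resolved ribosome density from 3'-end-mapped footprints.

Bacterial ribosome-profiling reads are mapped by their 3' ends, which sit a
fixed distance downstream of the decoded (A-site) codon.  Against a
transcriptome padded with 25 nt on both ends of each CDS, the A-site
nucleotide of a read is its 3'-end position minus a 37-nt offset (12 nt
ribosome geometry + 25 nt padding), and the codon containing that
nucleotide receives the count.  Per-gene counts are normalized to the
gene's total so every gene contributes a unit mass, and genome-wide codon
densities average those normalized densities over codon occurrences in
genes passing a minimum-read filter.

Stop-vs-sense contrasts of per-codon log2 fold-changes are tested with a
linear mixed model: fixed intercept (sense-codon mean shift) and stop
indicator (additional stop-codon shift), with uncorrelated per-line random
intercepts and slopes, selected by AIC against simpler and richer
structures.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))
STOP_CODONS: frozenset = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

__all__ = [
    "CODONS",
    "STOP_CODONS",
    "SENSE_CODONS",
    "RiboConfig",
    "CodonDensityProfile",
    "LmmFit",
    "assign_asite",
    "frame_periodicity",
    "codon_density_profile",
    "codon_fold_changes",
    "fit_stop_sense_lmm",
]


@dataclass(frozen=True)
class RiboConfig:
    """Fixed mapping and filtering parameters for footprint processing.

    ``offset_nt`` is measured on the padded transcript, so it must exceed
    ``padding_nt`` for the A-site to be able to land inside the CDS.
    """

    offset_nt: int = 37
    padding_nt: int = 25
    min_read_length: int = 24
    min_reads_per_gene: int = 100

    def __post_init__(self) -> None:
        if not self.offset_nt > self.padding_nt >= 0:
            raise ValueError("need offset_nt > padding_nt >= 0")
        if self.min_read_length <= 0 or self.min_reads_per_gene <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CodonDensityProfile:
    """Genome-wide mean normalized ribosome density per codon type.

    ``density`` is indexed by the 64 codons (NaN where a codon type never
    occurs in the qualifying gene set); ``per_gene_norm`` retains each
    qualifying gene's normalized per-codon vector for audit.
    """

    sample_id: str
    density: pd.Series
    n_qualifying: int
    per_gene_norm: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


@dataclass
class LmmFit:
    """Stop-vs-sense mixed-model fit with its AIC comparison table.

    beta0 is the population-level sense-codon mean log2 fold-change; beta1
    the additional stop-codon effect. ``line_effects`` holds the per-line
    predicted stop effects beta1 + b1_line.
    """

    beta0: float
    beta1: float
    beta0_pvalue: float
    beta1_pvalue: float
    line_effects: pd.Series
    resid_sd: float
    aic: float
    aic_table: pd.DataFrame
    structure: str
    converged: bool


def assign_asite(reads: pd.DataFrame, cds_lengths: dict[str, int], config: RiboConfig = RiboConfig()) -> dict:
    """Assign each footprint's A-site codon from its 3'-end position.

    ``reads`` has columns ``transcript_id``, ``three_prime_pos`` (1-based on
    the padded transcript) and ``read_length``.  A-site CDS nucleotide =
    three_prime_pos - offset_nt; codon index = ceil(position / 3). Reads
    shorter than the minimum length or with A-sites outside [1, CDS length]
    are discarded and counted.

    Returns a dict with ``counts`` (gene -> per-codon count vector),
    ``n_short``, ``n_outside`` and ``n_used``.
    """
    unknown = set(reads["transcript_id"].unique()) - set(cds_lengths)
    if unknown:
        raise KeyError(f"unknown transcript id(s): {sorted(unknown)[:5]}")
    bad_pos = ~np.isfinite(reads["three_prime_pos"].to_numpy(dtype=float))
    if bad_pos.any():
        warnings.warn(f"{int(bad_pos.sum())} reads with malformed positions skipped")
        reads = reads.loc[~bad_pos]
    long_enough = reads["read_length"] >= config.min_read_length
    n_short = int((~long_enough).sum())
    reads = reads.loc[long_enough]
    counts = {g: np.zeros(length // 3, dtype=np.int64) for g, length in cds_lengths.items()}
    cds_nt = reads["three_prime_pos"].to_numpy(dtype=np.int64) - config.offset_nt
    lens = reads["transcript_id"].map(cds_lengths).to_numpy(dtype=np.int64)
    inside = (cds_nt >= 1) & (cds_nt <= lens)
    n_outside = int((~inside).sum())
    codon_idx = (cds_nt[inside] - 1) // 3  # 0-based codon containing the A-site nt
    for gene, idx in zip(reads["transcript_id"].to_numpy()[inside], codon_idx):
        counts[gene][idx] += 1
    return {"counts": counts, "n_short": n_short, "n_outside": n_outside, "n_used": int(inside.sum())}


def frame_periodicity(
    reads: pd.DataFrame,
    cds_lengths: dict[str, int],
    config: RiboConfig = RiboConfig(),
    qc_threshold: float = 0.4,
) -> dict:
    """Fraction of A-site nucleotides in each reading frame.

    Frame 0 is the first nucleotide of a codon.  Footprint libraries show
    strong three-nucleotide periodicity, so the dominant-frame fraction is
    a basic QC readout; the verdict passes when it reaches ``qc_threshold``.
    """
    reads = reads.loc[reads["read_length"] >= config.min_read_length]
    cds_nt = reads["three_prime_pos"].to_numpy(dtype=np.int64) - config.offset_nt
    lens = reads["transcript_id"].map(cds_lengths).to_numpy(dtype=np.int64)
    cds_nt = cds_nt[(cds_nt >= 1) & (cds_nt <= lens)]
    if cds_nt.size == 0:
        raise ValueError("no valid reads for periodicity analysis")
    frames = (cds_nt - 1) % 3
    fractions = np.bincount(frames, minlength=3) / cds_nt.size
    return {
        "fractions": fractions,
        "dominant_frame": int(np.argmax(fractions)),
        "qc_pass": bool(fractions.max() >= qc_threshold),
        "n_reads": int(cds_nt.size),
    }


def codon_density_profile(
    counts: dict[str, np.ndarray],
    sequences: dict[str, str],
    config: RiboConfig = RiboConfig(),
    sample_id: str = "",
    average: str = "occurrence",
) -> CodonDensityProfile:
    """Genome-wide per-codon-type mean normalized ribosome density.

    Genes with at least ``min_reads_per_gene`` assigned reads qualify. Each
    qualifying gene's per-codon counts are divided by the gene total (so
    they sum to 1), and the genome-wide density of codon type c is the mean
    normalized density over all occurrences of c across qualifying genes
    (``average="occurrence"``), or the mean over genes of each gene's mean
    at c (``average="gene"``).
    """
    if average not in ("occurrence", "gene"):
        raise ValueError("average must be 'occurrence' or 'gene'")
    per_gene_norm: dict[str, np.ndarray] = {}
    values: dict[str, list] = {c: [] for c in CODONS}
    for gene, vec in counts.items():
        seq = sequences[gene].upper()
        if len(seq) != 3 * len(vec):
            raise ValueError(f"gene {gene}: sequence length inconsistent with count vector")
        total = vec.sum()
        if total < config.min_reads_per_gene:
            continue
        norm = vec / total
        per_gene_norm[gene] = norm
        codons = np.array([seq[i : i + 3] for i in range(0, len(seq), 3)])
        if average == "occurrence":
            for c in np.unique(codons):
                values[c].extend(norm[codons == c])
        else:
            for c in np.unique(codons):
                values[c].append(norm[codons == c].mean())
    if not per_gene_norm:
        raise ValueError("no genes pass the minimum-read filter")
    density = pd.Series(
        {c: (np.mean(v) if v else np.nan) for c, v in values.items()}, name=sample_id or "density"
    ).reindex(CODONS)
    return CodonDensityProfile(sample_id, density, len(per_gene_norm), per_gene_norm)


def codon_fold_changes(
    evolved: list[CodonDensityProfile], ancestor: list[CodonDensityProfile]
) -> pd.Series:
    """Per-codon-type log2 fold-change of mean evolved vs mean ancestor density.

    Codon types with zero or undefined density on either side are returned
    as NaN and logged as missing.
    """
    ev = pd.concat([p.density for p in evolved], axis=1).mean(axis=1)
    an = pd.concat([p.density for p in ancestor], axis=1).mean(axis=1)
    ok = (ev > 0) & (an > 0)
    if not ok.any():
        raise ValueError("no codon type has positive density on both sides")
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("%d codon types missing (zero/NaN density on one side)", n_missing)
    out = pd.Series(np.nan, index=ev.index, name="log2_fc")
    out[ok] = np.log2(ev[ok] / an[ok])
    return out


def _lmm_candidates(data: pd.DataFrame):
    import statsmodels.formula.api as smf

    opts = dict(reml=False, method=["lbfgs", "cg", "powell"])
    return {
        "ols": lambda: smf.ols("log2_fc ~ is_stop", data).fit(),
        "random_intercept": lambda: smf.mixedlm(
            "log2_fc ~ is_stop", data, groups=data["line"], re_formula="1"
        ).fit(**opts),
        "uncorrelated": lambda: smf.mixedlm(
            "log2_fc ~ is_stop",
            data,
            groups=data["line"],
            re_formula="1",
            vc_formula={"stop": "0 + is_stop"},
        ).fit(**opts),
        "correlated": lambda: smf.mixedlm(
            "log2_fc ~ is_stop", data, groups=data["line"], re_formula="1 + is_stop"
        ).fit(**opts),
    }


def fit_stop_sense_lmm(codon_fc: pd.DataFrame, structure: str = "uncorrelated") -> LmmFit:
    """Mixed-model test of whether stop codons shift differently from sense.

    ``codon_fc`` is long-format with columns ``codon``, ``line``,
    ``log2_fc`` (64 rows per line; NaN rows are dropped and logged). The
    response is the per-codon log2 density fold-change; fixed effects are
    an intercept (sense mean) and a stop-codon indicator; the requested
    random-effect structure (default: uncorrelated per-line intercepts and
    slopes) is fit by maximum likelihood alongside an AIC comparison
    against ordinary regression, a random-intercept-only model and a
    correlated intercept+slope model. A singular or non-converged requested
    structure is downgraded to the best-AIC non-singular candidate.
    """
    data = codon_fc.copy()
    if data["line"].nunique() < 2:
        raise ValueError("need at least 2 lines for random effects")
    n_na = int(data["log2_fc"].isna().sum())
    if n_na:
        logger.info("%d missing codon fold-changes dropped", n_na)
        data = data.dropna(subset=["log2_fc"])
    # canonical row order makes the optimizer path (hence the fit) invariant
    # to the order rows arrive in
    data = data.sort_values(["line", "codon"], kind="mergesort").reset_index(drop=True)
    data["is_stop"] = data["codon"].isin(STOP_CODONS).astype(float)
    fits: dict[str, object] = {}
    # materialize candidates first: importing statsmodels registers its own
    # warning filters, which must precede the suppression below
    candidates = _lmm_candidates(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, make in candidates.items():
            try:
                fits[name] = make()
            except Exception as exc:  # singular / non-convergent candidates
                logger.info("candidate %s failed to fit: %s", name, exc)
    rows = []
    for name, res in fits.items():
        converged = bool(getattr(res, "converged", True))
        rows.append({"structure": name, "aic": float(res.aic), "converged": converged})
    aic_table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    chosen = structure
    if chosen not in fits or not bool(getattr(fits[chosen], "converged", True)):
        ok = aic_table.loc[aic_table["converged"], "structure"]
        if ok.empty:
            raise RuntimeError("no candidate mixed-model structure converged")
        chosen = ok.iloc[0]
        logger.warning("requested structure %r unusable; downgraded to %r", structure, chosen)
    res = fits[chosen]
    params = res.params
    beta0 = float(params["Intercept"])
    beta1 = float(params["is_stop"])
    pvals = res.pvalues
    lines = sorted(data["line"].unique())
    if chosen == "ols":
        line_effects = pd.Series(beta1, index=lines)
        resid_sd = float(np.sqrt(res.scale))
    else:
        ranef = res.random_effects
        slopes = {}
        for line, eff in ranef.items():
            slope_keys = [k for k in eff.index if "stop" in k.lower()]
            slopes[line] = beta1 + (float(eff[slope_keys[0]]) if slope_keys else 0.0)
        line_effects = pd.Series(slopes).reindex(lines)
        resid_sd = float(np.sqrt(res.scale))
    return LmmFit(
        beta0=beta0,
        beta1=beta1,
        beta0_pvalue=float(pvals["Intercept"]),
        beta1_pvalue=float(pvals["is_stop"]),
        line_effects=line_effects,
        resid_sd=resid_sd,
        aic=float(res.aic),
        aic_table=aic_table,
        structure=chosen,
        converged=bool(getattr(res, "converged", True)),
    )
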