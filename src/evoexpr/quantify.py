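"""Core expression containers, TPM, DEG calling, and correlation profiles.

The central objects are a :class:`CountMatrix` (genes x samples with gene
lengths and sample metadata), a TPM :class:`AbundanceMatrix`, and a
long-format fold-change table with one row per (gene, line) carrying a
log2 fold-change, a q-value and a status flag (``measured``, ``deleted``
or ``indel``).  Deleted/indel genes have no fold-change or q-value; for
analyses that need a dense matrix they can be encoded with a fixed strongly
negative code via :func:`encode_deleted_fold_changes`.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FC_COLUMNS = ["gene_id", "line", "log2_fc", "q_value", "status"]
FC_STATUSES = frozenset({"measured", "deleted", "indel"})

__all__ = [
    "CountMatrix",
    "AbundanceMatrix",
    "DEGCallSet",
    "validate_fold_change_table",
    "compute_tpm",
    "call_degs",
    "encode_deleted_fold_changes",
    "correlation_profiles",
    "direction_asymmetry_tests",
]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with gene lengths and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
        Every sample carries the identical gene complement; genes absent
        from a line's transcriptome are zero-padded rows.
    lengths
        Gene lengths in nucleotides, indexed like ``counts``.
    samples
        Per-sample metadata indexed by sample id with at least the columns
        ``line``, ``replicate``, ``assay`` and ``is_ancestor``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.lengths, self.samples.loc[list(sample_ids)]
        )


@dataclass
class AbundanceMatrix:
    """Genes x samples TPM values; every column sums to 1e6."""

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.tpm.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValueError("TPM columns must each sum to 1e6")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.tpm.columns


@dataclass
class DEGCallSet:
    """Per-line up/down differentially expressed gene sets.

    ``u(line)`` and ``d(line)`` are the per-line up/down counts that
    parameterize the cross-line parallelism null; ``n_genes`` is the total
    gene complement G against which the per-line hit probabilities
    u_i/G and d_i/G are formed.
    """

    up_genes: dict[str, frozenset]
    down_genes: dict[str, frozenset]
    n_genes: int
    q_threshold: float
    n_zero_fc_significant: int = 0

    def __post_init__(self) -> None:
        for line in self.up_genes:
            overlap = self.up_genes[line] & self.down_genes[line]
            if overlap:
                raise ValueError(f"gene(s) both up and down in line {line}: {sorted(overlap)[:3]}")
            if len(self.up_genes[line]) + len(self.down_genes[line]) > self.n_genes:
                raise ValueError("more DEGs than genes")

    @property
    def lines(self) -> list[str]:
        return list(self.up_genes)

    def u(self, line: str) -> int:
        return len(self.up_genes[line])

    def d(self, line: str) -> int:
        return len(self.down_genes[line])


def validate_fold_change_table(fc: pd.DataFrame) -> pd.DataFrame:
    """Check the (gene, line) fold-change table schema and invariants."""
    missing = [c for c in FC_COLUMNS if c not in fc.columns]
    if missing:
        raise ValueError(f"fold-change table missing columns: {missing}")
    bad_status = set(fc["status"].unique()) - FC_STATUSES
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    measured = fc["status"] == "measured"
    if fc.loc[measured, ["log2_fc", "q_value"]].isna().any().any():
        raise ValueError("measured rows must carry log2_fc and q_value")
    if fc.loc[~measured, ["log2_fc", "q_value"]].notna().any().any():
        raise ValueError("deleted/indel rows must not carry log2_fc or q_value")
    q = fc.loc[measured, "q_value"]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q-values must lie in [0, 1]")
    if fc.duplicated(["gene_id", "line"]).any():
        raise ValueError("duplicate (gene, line) rows")
    return fc


def compute_tpm(counts: CountMatrix) -> AbundanceMatrix:
    """Transcripts per million: length-normalized read rates scaled to 1e6.

    TPM_g = 1e6 * (count_g / length_g) / sum_j (count_j / length_j), per
    sample, so each sample column sums to one million by construction.
    """
    rates = counts.counts.div(counts.lengths, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    return AbundanceMatrix(rates.div(totals, axis=1) * 1e6)


def call_degs(fc: pd.DataFrame, q_threshold: float = 0.01) -> DEGCallSet:
    """Call per-line up/down DEGs at an inclusive q-value threshold.

    A gene is up in a line iff it is measured there with q <= threshold and
    log2_fc > 0 (down analogously). Deleted/indel rows never qualify.
    Measured rows with q <= threshold but log2_fc exactly 0 belong to
    neither direction; they are counted and logged.
    """
    validate_fold_change_table(fc)
    n_genes = fc["gene_id"].nunique()
    sig = (fc["status"] == "measured") & (fc["q_value"] <= q_threshold)
    zero_sig = int((sig & (fc["log2_fc"] == 0)).sum())
    if zero_sig:
        logger.warning("%d significant rows with log2_fc == 0 excluded from both directions", zero_sig)
    up: dict[str, frozenset] = {}
    down: dict[str, frozenset] = {}
    for line, sub in fc.groupby("line", sort=False):
        s = sig.loc[sub.index]
        up[line] = frozenset(sub.loc[s & (sub["log2_fc"] > 0), "gene_id"])
        down[line] = frozenset(sub.loc[s & (sub["log2_fc"] < 0), "gene_id"])
    return DEGCallSet(up, down, n_genes, q_threshold, zero_sig)


def encode_deleted_fold_changes(fc: pd.DataFrame, deletion_code: float = -10.0) -> pd.DataFrame:
    """Dense gene x line log2FC matrix with deletions/indels set to a code.

    Genes lost to deletions or indels produce no functional transcript, so
    for dense analyses (PCA, pathway scores) they are encoded as severe
    downregulation — by default log2FC = -10.
    """
    validate_fold_change_table(fc)
    mat = fc.pivot(index="gene_id", columns="line", values="log2_fc")
    status = fc.pivot(index="gene_id", columns="line", values="status")
    mat = mat.mask(status.isin(["deleted", "indel"]), deletion_code)
    return mat


def correlation_profiles(
    values: pd.DataFrame,
    grouping: pd.Series | dict,
    method: str = "pearson",
    gene_subset=None,
) -> dict:
    """All pairwise column correlations, split evolved-evolved vs ancestor-evolved.

    Parameters
    ----------
    values
        Genes x columns matrix (e.g. log10 TPM per line, or fold-changes).
        Rows with NaN in a pair are dropped pairwise.
    grouping
        Column label -> ``"ancestor"`` or ``"evolved"``.
    method
        ``"pearson"`` or ``"spearman"``.
    gene_subset
        Optional gene set; correlations are computed on the intersection.

    Returns a dict with the per-pair table (``pairs``), and the two-sample
    KS statistic/p-value comparing the evolved-evolved correlation
    distribution against the ancestor-evolved one.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    if values.shape[1] < 2:
        raise ValueError("need at least two columns")
    if gene_subset is not None:
        keep = values.index.intersection(list(gene_subset))
        if len(keep) == 0:
            raise ValueError("gene_subset has empty intersection with the matrix")
        values = values.loc[keep]
    # log-scale inputs can carry -inf for zero-TPM genes; treat them like
    # missing values so they are dropped pairwise (and counted via n_genes)
    n_inf = int(np.isinf(values.to_numpy()).sum())
    if n_inf:
        logger.info("%d non-finite values treated as missing (zero TPM under log?)", n_inf)
        values = values.replace([np.inf, -np.inf], np.nan)
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for a, b in itertools.combinations(values.columns, 2):
        cls = _pair_class(grouping[a], grouping[b])
        sub = values[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() == 1 or sub[b].nunique() == 1:
            logger.warning("pair (%s, %s): constant or degenerate column, excluded", a, b)
            rows.append({"col_a": a, "col_b": b, "cls": cls, "r": np.nan, "n_genes": len(sub)})
            continue
        r = corr_fn(sub[a], sub[b])[0]
        rows.append({"col_a": a, "col_b": b, "cls": cls, "r": r, "n_genes": len(sub)})
    pairs = pd.DataFrame(rows)
    ev = pairs.loc[(pairs["cls"] == "evolved-evolved") & pairs["r"].notna(), "r"]
    anc = pairs.loc[(pairs["cls"] == "ancestor-evolved") & pairs["r"].notna(), "r"]
    if len(ev) and len(anc):
        ks = stats.ks_2samp(ev, anc)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat = ks_p = float("nan")
    return {"pairs": pairs, "ks_statistic": ks_stat, "ks_pvalue": ks_p}


def _pair_class(ga: str, gb: str) -> str:
    if ga == "evolved" and gb == "evolved":
        return "evolved-evolved"
    if "ancestor" in (ga, gb) and "evolved" in (ga, gb):
        return "ancestor-evolved"
    return "ancestor-ancestor"


def direction_asymmetry_tests(deg: DEGCallSet, fc: pd.DataFrame) -> pd.DataFrame:
    """Per-line tests for up/down asymmetry in DEG counts and magnitudes.

    For each line: a two-sided exact binomial test of the up count against
    a null proportion of 0.5, and a two-sample KS test comparing |log2FC|
    of up-regulated vs down-regulated DEGs. Lines with zero DEGs are
    skipped with a warning.
    """
    validate_fold_change_table(fc)
    rows = []
    for line in deg.lines:
        u, d = deg.u(line), deg.d(line)
        if u + d == 0:
            warnings.warn(f"line {line} has no DEGs; skipped")
            continue
        binom_p = stats.binomtest(u, u + d, 0.5).pvalue
        sub = fc[(fc["line"] == line) & (fc["status"] == "measured")].set_index("gene_id")
        up_mag = sub.loc[list(deg.up_genes[line]), "log2_fc"].abs()
        down_mag = sub.loc[list(deg.down_genes[line]), "log2_fc"].abs()
        if len(up_mag) and len(down_mag):
            ks = stats.ks_2samp(up_mag, down_mag)
            ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
        else:
            ks_stat = ks_p = float("nan")
        rows.append(
            {
                "line": line,
                "n_up": u,
                "n_down": d,
                "binom_pvalue": float(binom_p),
                "ks_statistic": ks_stat,
                "ks_pvalue": ks_p,
            }
        )
    return pd.DataFrame(rows)
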