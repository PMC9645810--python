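"""Synthetic data generators with known ground truth for every pipeline stage.

The generators emulate the structure of a multi-line experimental-evolution
expression study: several evolved lines with replicate RNA-seq/Ribo-seq
libraries compared against ancestor samples, with a configurable number of
true differentially expressed genes (DEGs) per line, cross-line sharing of
DEG identities, direction concordance, and per-line gene deletions.  Around
that sit generators for spike-in observations from a known log-linear
calibration, ribosome footprints placed with a known A-site offset, frame
periodicity and per-codon dwell weights, per-(codon, line) fold-changes
from a known mixed model, toy pathway maps, and cell-geometry /
sample-metadata tables.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import CountMatrix
from .ribo import CODONS, SENSE_CODONS, STOP_CODONS

__all__ = [
    "SimConfig",
    "FootprintSimConfig",
    "simulate_fold_change_table",
    "simulate_counts",
    "default_spikein_design",
    "simulate_spikein_counts",
    "simulate_cds_sequences",
    "simulate_footprints",
    "simulate_codon_fc_table",
    "simulate_pathway_map",
    "simulate_cell_geometry",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the multi-line expression simulation.

    Defaults mirror the scale of the emulated study: 11 evolved lines with
    2 replicates each, 4 ancestor samples, 4131 genes and ~270 true DEGs
    per line.  ``nb_dispersion`` is the negative-binomial dispersion in the
    RNA-seq convention variance = mean + mean^2 * dispersion.
    """

    n_genes: int = 4131
    n_lines: int = 11
    n_replicates: int = 2
    n_ancestor_samples: int = 4
    nb_mean: float = 500.0
    nb_dispersion: float = 0.05
    deg_per_line: int = 270
    shared_fraction: float = 0.5
    direction_concordance: float = 0.9
    effect_size_log2: float = 1.0
    deletion_per_line: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_lines", "n_replicates", "n_ancestor_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.deg_per_line < 0 or self.deletion_per_line < 0:
            raise ValueError("per-line DEG and deletion counts must be non-negative")
        if self.deg_per_line + self.deletion_per_line > self.n_genes:
            raise ValueError("deg_per_line + deletion_per_line exceeds n_genes")
        for name in ("shared_fraction", "direction_concordance"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0 or self.nb_mean <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_lines)]


@dataclass(frozen=True)
class FootprintSimConfig:
    """Parameters of the footprint generator, the inverse of A-site mapping.

    Reads are placed so that the 3' end sits ``offset_nt`` downstream of
    the A-site nucleotide on the padded transcript (CDS flanked by
    ``padding_nt`` on both sides); off-frame jitter moves the 3' end by
    +/- 1 nt with probability 1 - frame0_fraction.
    """

    sequences: dict  # gene -> CDS string, length divisible by 3
    padding_nt: int = 25
    offset_nt: int = 37
    frame0_fraction: float = 1.0
    dwell_weights: pd.Series | None = None  # per codon type, 64 strictly positive values
    reads_per_gene: int = 1000
    read_length_range: tuple[int, int] = (24, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.padding_nt < 0 or self.offset_nt <= self.padding_nt:
            raise ValueError("need offset_nt > padding_nt >= 0")
        if not (1.0 / 3.0) <= self.frame0_fraction <= 1.0:
            raise ValueError("frame0_fraction must lie in [1/3, 1]")
        for gene, seq in self.sequences.items():
            if len(seq) % 3 != 0:
                raise ValueError(f"gene {gene}: CDS length not divisible by 3")
        if self.dwell_weights is not None:
            w = pd.Series(self.dwell_weights).reindex(CODONS)
            if w.isna().any() or (w <= 0).any():
                raise ValueError("dwell_weights must cover all 64 codons with positive values")
        lo, hi = self.read_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid read_length_range")
        if self.reads_per_gene < 1:
            raise ValueError("reads_per_gene must be positive")

    def weights(self) -> pd.Series:
        if self.dwell_weights is None:
            return pd.Series(1.0, index=pd.Index(CODONS))
        return pd.Series(self.dwell_weights).reindex(CODONS).astype(float)


def simulate_fold_change_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One fold-change/q-value row per (gene, line) plus the ground truth.

    True DEGs are drawn per line: a fixed shared pool of
    round(shared_fraction * deg_per_line) genes appears in every line
    (keeping its pool direction with probability ``direction_concordance``),
    and the remainder is line-private.  True DEGs receive a signed log2
    fold-change with mean magnitude ``effect_size_log2`` and a q-value
    safely below 0.01; non-DEGs get near-zero fold-changes and uniform
    q-values; deleted genes get status ``deleted`` with no fold-change.

    Returns ``(fc_table, truth)`` where ``truth`` marks per (gene, line)
    whether the gene is a true DEG, its true direction and effect.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array(config.gene_ids)
    k_shared = int(round(config.shared_fraction * config.deg_per_line))
    pool = rng.choice(genes, size=k_shared, replace=False)
    pool_dir = rng.choice([-1, 1], size=k_shared)
    non_pool = np.setdiff1d(genes, pool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    frames, truth_frames = [], []
    for line in config.line_ids:
        deleted = rng.choice(non_pool, size=config.deletion_per_line, replace=False)
        candidates = np.setdiff1d(non_pool, deleted)
        private = rng.choice(candidates, size=config.deg_per_line - k_shared, replace=False)
        keep = rng.random(k_shared) < config.direction_concordance
        deg_genes = np.concatenate([pool, private])
        deg_dir = np.concatenate(
            [np.where(keep, pool_dir, -pool_dir), rng.choice([-1, 1], size=private.size)]
        ).astype(int)
        deg_fc = deg_dir * rng.gamma(2.0, config.effect_size_log2 / 2.0, size=deg_genes.size)
        log2_fc = rng.normal(0.0, 0.05, size=config.n_genes)
        q = rng.uniform(0.0, 1.0, size=config.n_genes)
        status = np.full(config.n_genes, "measured", dtype=object)
        is_deg = np.zeros(config.n_genes, dtype=bool)
        direction = np.zeros(config.n_genes, dtype=int)
        deg_idx = np.array([gene_pos[g] for g in deg_genes], dtype=int)
        log2_fc[deg_idx] = deg_fc
        q[deg_idx] = rng.uniform(0.0, 0.009, size=deg_idx.size)
        is_deg[deg_idx] = True
        direction[deg_idx] = deg_dir
        del_idx = np.array([gene_pos[g] for g in deleted], dtype=int)
        true_fc = np.where(is_deg, log2_fc, 0.0)
        log2_fc[del_idx] = np.nan
        q[del_idx] = np.nan
        status[del_idx] = "deleted"
        is_deleted = np.zeros(config.n_genes, dtype=bool)
        is_deleted[del_idx] = True
        frames.append(
            pd.DataFrame(
                {"gene_id": genes, "line": line, "log2_fc": log2_fc, "q_value": q, "status": status}
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "line": line,
                    "is_deg": is_deg,
                    "direction": direction,
                    "true_log2_fc": true_fc,
                    "is_deleted": is_deleted,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), pd.concat(truth_frames, ignore_index=True)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + mean^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p, size=int(pos.sum()))
    return out


def simulate_counts(config: SimConfig, fold_changes: pd.DataFrame) -> tuple[CountMatrix, CountMatrix]:
    """Negative-binomial RNA and Ribo count matrices consistent with a
    fold-change table.

    Per-gene baseline means are lognormal around ``nb_mean``; evolved-line
    means are the baseline scaled by 2^log2FC, deleted genes are all-zero
    in their line, and Ribo counts share the RNA means (no translational
    changes by default) but are drawn independently.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = config.gene_ids
    lines = config.line_ids
    fc_lines = set(fold_changes["line"].unique())
    if not set(lines) <= fc_lines or fold_changes["gene_id"].nunique() != config.n_genes:
        raise ValueError("fold-change table inconsistent with config dimensions")
    base = rng.lognormal(np.log(config.nb_mean) - 0.5, 1.0, size=config.n_genes)
    lengths = pd.Series(
        rng.integers(300, 3000, size=config.n_genes) // 3 * 3,
        index=pd.Index(genes, name="gene_id"),
        name="length",
    )
    log2fc = fold_changes.pivot(index="gene_id", columns="line", values="log2_fc").reindex(genes)
    status = fold_changes.pivot(index="gene_id", columns="line", values="status").reindex(genes)
    sample_ids, meta_rows, mean_cols = [], [], []
    for i in range(config.n_ancestor_samples):
        sid = f"anc_r{i + 1}"
        sample_ids.append(sid)
        meta_rows.append((sid, "ancestor", i + 1, True))
        mean_cols.append(base)
    for line in lines:
        scale = np.where(status[line] == "measured", 2.0 ** log2fc[line].fillna(0.0), 0.0)
        for rep in range(config.n_replicates):
            sid = f"{line}_r{rep + 1}"
            sample_ids.append(sid)
            meta_rows.append((sid, line, rep + 1, False))
            mean_cols.append(base * scale)
    means = np.column_stack(mean_cols)
    rna = np.column_stack([_nb_draw(rng, means[:, j], config.nb_dispersion) for j in range(means.shape[1])])
    ribo = np.column_stack([_nb_draw(rng, means[:, j], config.nb_dispersion) for j in range(means.shape[1])])
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "line", "replicate", "is_ancestor"]).set_index("sample_id")
    meta["cfu"] = rng.lognormal(np.log(1e8), 0.1, size=len(meta))
    rna_meta, ribo_meta = meta.copy(), meta.copy()
    rna_meta["assay"] = "rna"
    ribo_meta["assay"] = "ribo"
    make = lambda arr, m: CountMatrix(
        pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=sample_ids), lengths, m
    )
    return make(rna, rna_meta), make(ribo, ribo_meta)


def default_spikein_design(sample_ids, n_spikeins: int = 92, seed: int = 0) -> pd.DataFrame:
    """Spike-in design table: molecule inputs log-spaced over six decades,
    identical across samples (one mix added to every library)."""
    rng = np.random.default_rng(seed)
    molecules = 10.0 ** rng.uniform(0.5, 6.5, size=n_spikeins)
    rows = [
        {"spikein_id": f"spike_{i:03d}", "sample_id": sid, "molecules": molecules[i]}
        for sid in sample_ids
        for i in range(n_spikeins)
    ]
    return pd.DataFrame(rows)


def simulate_spikein_counts(
    design: pd.DataFrame, slope: float = 1.0, intercept: float = -3.0, noise_sd: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Observed TPM-scale spike-in values from a log-linear observation model.

    log10(observed) = intercept + slope * log10(molecules) + N(0, noise_sd),
    independently per spike-in per sample. Returns a spike-in x sample
    DataFrame alignable with :func:`evoexpr.absolute.fit_spikein_calibration`.
    """
    if (design["molecules"] <= 0).any():
        raise ValueError("spike-in molecule counts must be positive")
    rng = np.random.default_rng(seed)
    obs = design.copy()
    log10_obs = intercept + slope * np.log10(obs["molecules"].to_numpy())
    log10_obs = log10_obs + rng.normal(0.0, noise_sd, size=len(obs))
    obs["observed"] = 10.0**log10_obs
    return obs.pivot(index="spikein_id", columns="sample_id", values="observed")


def simulate_cds_sequences(n_genes: int, n_codons_range: tuple[int, int] = (60, 300), seed: int = 0) -> dict:
    """Random coding sequences: ATG start, sense body, one stop codon."""
    rng = np.random.default_rng(seed)
    sense = np.array(SENSE_CODONS)
    stops = np.array(sorted(STOP_CODONS))
    seqs = {}
    for i in range(n_genes):
        n_codons = int(rng.integers(n_codons_range[0], n_codons_range[1] + 1))
        body = rng.choice(sense, size=n_codons - 2)
        seqs[f"g{i:05d}"] = "ATG" + "".join(body) + str(rng.choice(stops))
    return seqs


def simulate_footprints(config: FootprintSimConfig) -> pd.DataFrame:
    """Footprint reads whose 3' ends invert the A-site assignment rule.

    For each read the A-site codon is drawn proportional to the dwell
    weights over the gene's codons; the 3' end is placed at the codon's
    first nucleotide plus ``offset_nt`` (1-based padded coordinates), then
    jittered off-frame by +/- 1 nt with probability 1 - frame0_fraction.
    Placements falling outside the padded transcript are resampled.

    Returns a DataFrame with columns ``transcript_id``, ``three_prime_pos``
    and ``read_length``.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.weights()
    lo, hi = config.read_length_range
    frames = []
    for gene, seq in config.sequences.items():
        seq = seq.upper()
        n_codons = len(seq) // 3
        padded_len = len(seq) + 2 * config.padding_nt
        codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]
        w = weights[codons].to_numpy()
        probs = w / w.sum()
        codon_idx = rng.choice(n_codons, size=config.reads_per_gene, p=probs)
        cds_nt = 3 * codon_idx + 1  # first nucleotide of the A-site codon, 1-based
        jitter_mask = rng.random(config.reads_per_gene) >= config.frame0_fraction
        jitter = np.where(rng.random(config.reads_per_gene) < 0.5, -1, 1) * jitter_mask
        # A-site assignment computes CDS nt = padded 3' position - offset_nt,
        # so the emitted position is its inverse: cds_nt + offset_nt.
        pos = cds_nt + jitter + config.offset_nt
        for _ in range(100):
            bad = (pos < 1) | (pos > padded_len)
            if not bad.any():
                break
            pos[bad] = cds_nt[bad] + config.offset_nt
        lengths = rng.integers(lo, hi + 1, size=config.reads_per_gene)
        lengths = np.minimum(lengths, pos)  # 5' end cannot precede the transcript start
        frames.append(
            pd.DataFrame(
                {"transcript_id": gene, "three_prime_pos": pos, "read_length": lengths}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_codon_fc_table(
    beta0: float = 0.0,
    beta1: float = -0.325,
    line_sd_intercept: float = 0.05,
    line_sd_slope: float = 0.1,
    resid_sd: float = 0.1,
    n_lines: int = 11,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(codon, line) log2 fold-changes from a known mixed model.

    log2FC(codon, line) = (beta0 + b0_line) + (beta1 + b1_line) * is_stop
    + N(0, resid_sd), with uncorrelated b0 ~ N(0, line_sd_intercept^2) and
    b1 ~ N(0, line_sd_slope^2); 61 sense and 3 stop codons per line.
    """
    if min(line_sd_intercept, line_sd_slope, resid_sd) < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_lines < 2:
        raise ValueError("need at least 2 lines (random effects unidentifiable)")
    rng = np.random.default_rng(seed)
    is_stop = np.array([c in STOP_CODONS for c in CODONS], dtype=float)
    rows = []
    for i in range(n_lines):
        line = f"L{i + 1:02d}"
        b0 = rng.normal(0.0, line_sd_intercept)
        b1 = rng.normal(0.0, line_sd_slope)
        y = (beta0 + b0) + (beta1 + b1) * is_stop + rng.normal(0.0, resid_sd, size=len(CODONS))
        rows.append(pd.DataFrame({"codon": CODONS, "line": line, "log2_fc": y}))
    return pd.concat(rows, ignore_index=True)


def simulate_pathway_map(
    n_pathways: int,
    reactions_per_pathway: tuple[int, int],
    enzymes_per_reaction: tuple[int, int],
    gene_pool,
    seed: int = 0,
):
    """Toy pathway map: every pathway gets >= 1 reaction, every reaction
    >= 1 enzyme drawn without replacement (within a reaction) from the pool."""
    from .pathways import PathwayMap

    gene_pool = list(gene_pool)
    if not gene_pool:
        raise ValueError("gene pool must be non-empty")
    r_lo, r_hi = reactions_per_pathway
    e_lo, e_hi = enzymes_per_reaction
    if r_lo < 1 or r_hi < r_lo or e_lo < 1 or e_hi < e_lo:
        raise ValueError("reaction/enzyme ranges must be non-empty with positive lower bounds")
    rng = np.random.default_rng(seed)
    pathways, reactions = {}, {}
    for i in range(n_pathways):
        pw = f"pw{i:03d}"
        n_rxn = int(rng.integers(r_lo, r_hi + 1))
        ids = []
        for j in range(n_rxn):
            rid = f"{pw}_rxn{j:02d}"
            n_enz = min(int(rng.integers(e_lo, e_hi + 1)), len(gene_pool))
            enzymes = rng.choice(gene_pool, size=n_enz, replace=False)
            reactions[rid] = frozenset(enzymes)
            ids.append(rid)
        pathways[pw] = tuple(ids)
    return PathwayMap(pathways, reactions)


def simulate_cell_geometry(
    line_ids,
    mean_lengths=None,
    mean_width: float = 1.0,
    n_cells: int = 100,
    cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell length/width measurements for each line.

    ``mean_lengths`` maps line -> mean cell length in um (default: 3 um for
    every line); widths are lognormal around ``mean_width`` and lengths are
    clipped to stay >= width so the spherocylinder geometry is valid.
    """
    rng = np.random.default_rng(seed)
    line_ids = list(line_ids)
    if mean_lengths is None:
        mean_lengths = {ln: 3.0 for ln in line_ids}
    rows = []
    for ln in line_ids:
        sigma = np.sqrt(np.log(1 + cv**2))
        lengths = rng.lognormal(np.log(mean_lengths[ln]) - sigma**2 / 2, sigma, size=n_cells)
        widths = rng.lognormal(np.log(mean_width) - sigma**2 / 2, sigma, size=n_cells)
        lengths = np.maximum(lengths, widths)
        for k in range(n_cells):
            rows.append({"line": ln, "cell_id": f"{ln}_c{k:04d}", "length_um": lengths[k], "width_um": widths[k]})
    return pd.DataFrame(rows)
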