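"""Pathway perturbation scoring with a permutation null.

A pathway is an ordered list of reactions; each reaction is completed by
one or more enzymes. The reaction perturbation score (RPS) is the largest
absolute enzyme log2 fold-change for the reaction; the pathway perturbation
score (PPS) for a pathway with N scored reactions is the root mean square
sqrt(sum(RPS^2) / N). PPS measures how strongly a pathway is altered but
not in which direction. With the deletion encoding (deleted genes at
log2FC = -10), a deleted enzyme dominates its reaction's score.

Cross-line parallelism of pathway alteration is assessed by Spearman
correlations between the per-line PPS vectors, against a null built by
repeatedly shuffling gene labels of each line's fold-change vector and
recomputing all PPS and correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayMap",
    "reaction_perturbation_scores",
    "pathway_perturbation_score",
    "pps_table",
    "pps_randomization_null",
]


@dataclass(frozen=True)
class PathwayMap:
    """pathway id -> ordered reactions; reaction id -> enzyme gene ids."""

    pathways: dict  # pathway_id -> tuple of reaction ids
    reactions: dict  # reaction_id -> frozenset of enzyme gene ids

    def __post_init__(self) -> None:
        for pw, rxns in self.pathways.items():
            if len(rxns) == 0:
                raise ValueError(f"pathway {pw} has no reactions")
            for r in rxns:
                if r not in self.reactions:
                    raise ValueError(f"pathway {pw} references unknown reaction {r}")
        for r, enzymes in self.reactions.items():
            if len(enzymes) == 0:
                raise ValueError(f"reaction {r} has no enzymes")

    @classmethod
    def from_dict(cls, obj: dict) -> "PathwayMap":
        """Build from ``{"pw": [{"reaction": "r1", "enzymes": ["gA"]}, ...]}``."""
        pathways, reactions = {}, {}
        for pw, rxns in obj.items():
            ids = []
            for entry in rxns:
                rid = entry["reaction"]
                ids.append(rid)
                reactions[rid] = frozenset(entry["enzymes"])
            pathways[pw] = tuple(ids)
        return cls(pathways, reactions)

    def to_dict(self) -> dict:
        return {
            pw: [{"reaction": r, "enzymes": sorted(self.reactions[r])} for r in rxns]
            for pw, rxns in self.pathways.items()
        }

    @property
    def enzymes(self) -> frozenset:
        return frozenset().union(*self.reactions.values())


def reaction_perturbation_scores(pmap: PathwayMap, fc: pd.Series, pathway_id: str) -> pd.Series:
    """RPS per reaction of one pathway: max over enzymes of |log2FC|.

    ``fc`` is a dense per-gene fold-change vector for one line (deletions
    already encoded). Enzymes absent from the vector are skipped and
    logged; a reaction with no scorable enzyme gets NaN and is excluded
    from the pathway's N. A pathway in which no reaction is scorable is an
    error.
    """
    rxns = pmap.pathways[pathway_id]
    scores = {}
    n_missing = 0
    for r in rxns:
        vals = []
        for enz in pmap.reactions[r]:
            if enz in fc.index and pd.notna(fc[enz]):
                vals.append(abs(float(fc[enz])))
            else:
                n_missing += 1
        scores[r] = max(vals) if vals else np.nan
    if n_missing:
        logger.info("pathway %s: %d enzyme(s) missing from the fold-change vector", pathway_id, n_missing)
    out = pd.Series(scores, name=pathway_id).reindex(list(rxns))
    if out.isna().all():
        raise ValueError(f"pathway {pathway_id}: no reaction has a scorable enzyme")
    return out


def pathway_perturbation_score(rps) -> float:
    """Root mean square of a pathway's defined reaction perturbation scores."""
    vals = np.asarray(pd.Series(rps).dropna(), dtype=float)
    if vals.size == 0:
        raise ValueError("no defined RPS values")
    if (vals < 0).any():
        raise ValueError("RPS values must be non-negative")
    return float(np.sqrt(np.mean(vals**2)))


class _PathwayIndex:
    """Gene-position index of a pathway map against a fixed gene ordering,
    so PPS for a whole matrix reduces to numpy segment maxima."""

    def __init__(self, pmap: PathwayMap, gene_index: pd.Index):
        pos = pd.Series(np.arange(len(gene_index)), index=gene_index)
        self.pathway_ids = list(pmap.pathways)
        self.reaction_enzyme_idx: list[list[np.ndarray]] = []
        n_missing = 0
        for pw in self.pathway_ids:
            rxn_idx = []
            for r in pmap.pathways[pw]:
                enzymes = [e for e in pmap.reactions[r] if e in pos.index]
                n_missing += len(pmap.reactions[r]) - len(enzymes)
                rxn_idx.append(pos[enzymes].to_numpy() if enzymes else np.array([], dtype=int))
            if all(idx.size == 0 for idx in rxn_idx):
                raise ValueError(f"pathway {pw}: no reaction has a scorable enzyme")
            self.reaction_enzyme_idx.append(rxn_idx)
        if n_missing:
            logger.info("%d enzyme occurrences missing from the fold-change matrix", n_missing)

    def pps(self, values: np.ndarray) -> np.ndarray:
        """PPS matrix (pathways x lines) for a dense gene x line array."""
        absv = np.abs(values)
        out = np.empty((len(self.pathway_ids), values.shape[1]))
        for i, rxn_idx in enumerate(self.reaction_enzyme_idx):
            sq_sum = np.zeros(values.shape[1])
            n = np.zeros(values.shape[1])
            for idx in rxn_idx:
                if idx.size == 0:
                    continue
                with np.errstate(invalid="ignore"):
                    rps = np.nanmax(absv[idx, :], axis=0) if np.isnan(values[idx, :]).any() else absv[idx, :].max(axis=0)
                ok = ~np.isnan(rps)
                sq_sum[ok] += rps[ok] ** 2
                n[ok] += 1
            out[i] = np.sqrt(sq_sum / np.maximum(n, 1))
            out[i, n == 0] = np.nan
        return out


def pps_table(pmap: PathwayMap, fc_matrix: pd.DataFrame) -> pd.DataFrame:
    """PPS per (pathway, line) for a dense gene x line fold-change matrix."""
    index = _PathwayIndex(pmap, fc_matrix.index)
    vals = index.pps(fc_matrix.to_numpy(dtype=float))
    return pd.DataFrame(vals, index=pd.Index(index.pathway_ids, name="pathway"), columns=fc_matrix.columns)


def _pairwise_spearman(pps_values: np.ndarray) -> np.ndarray:
    """Spearman correlations over all unordered column pairs, NaN for
    pairs involving a constant vector (flagged)."""
    n_col = pps_values.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 0, pps_values)
    constant = ranks.std(axis=0) == 0
    if constant.any():
        logger.warning("%d constant PPS vector(s); affected pairs flagged as NaN", int(constant.sum()))
    with np.errstate(invalid="ignore"):
        cmat = np.corrcoef(ranks, rowvar=False)
    cmat[constant, :] = np.nan
    cmat[:, constant] = np.nan
    iu = np.triu_indices(n_col, k=1)
    return cmat[iu]


def pps_randomization_null(
    pmap: PathwayMap,
    fc_matrix: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Observed cross-line PPS correlations against a gene-shuffling null.

    Observed values are the Spearman correlations of pathway-indexed PPS
    vectors over all line pairs. Each permutation independently shuffles
    the gene labels of every line's fold-change vector (preserving each
    line's fold-change distribution while destroying pathway membership and
    cross-line gene identity), recomputes every PPS and every pairwise
    correlation. A two-sample KS test compares the observed correlation
    set with the pooled null set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if fc_matrix.shape[1] < 2:
        raise ValueError("need at least 2 lines")
    if len(pmap.pathways) < 2:
        raise ValueError("need at least 2 pathways")
    rng = np.random.default_rng(seed)
    index = _PathwayIndex(pmap, fc_matrix.index)
    values = fc_matrix.to_numpy(dtype=float)
    observed = _pairwise_spearman(index.pps(values))
    null = np.empty((n_perm, observed.size))
    shuffled = np.empty_like(values)
    for k in range(n_perm):
        for j in range(values.shape[1]):
            shuffled[:, j] = values[rng.permutation(values.shape[0]), j]
        null[k] = _pairwise_spearman(index.pps(shuffled))
    obs_ok = observed[~np.isnan(observed)]
    null_ok = null.ravel()[~np.isnan(null.ravel())]
    if obs_ok.size == 0 or null_ok.size == 0:
        raise ValueError("no finite correlations to compare")
    ks = stats.ks_2samp(obs_ok, null_ok)
    return {
        "observed": observed,
        "null": null,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_perm": n_perm,
    }
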