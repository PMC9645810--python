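"""Cross-line expression parallelism: exact nulls and observed profiles.

For L evolved lines, each gene has a count x = number of lines in which it
is both significant (q <= threshold) and changed in the same direction.
Under the null that each line's u_i up- and d_i down-regulated hits fall on
random genes, the number of lines with a same-direction hit for a random
gene follows a distribution built from sums of independent non-identical
binomial (SINIB / Poisson-binomial) variables:

* ``sinib_independent`` — X_up ~ PoissonBinomial(u_i/G), X_down ~
  PoissonBinomial(d_i/G), treated as independent; x = max(X_up, X_down).
  This mirrors the classical SINIB construction, at the cost of allowing a
  gene to be simultaneously up and down in one line.
* ``trinomial_exact`` — a dynamic program over lines on the joint
  (n_up, n_down) state with per-line trinomial cell probabilities
  (u_i/G, d_i/G, remainder), which enforces mutual exclusivity.

The observed per-gene x values are compared to the null with a one-sample
KS test on the support restricted to x >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .quantify import DEGCallSet, call_degs, validate_fold_change_table

logger = logging.getLogger(__name__)

__all__ = [
    "SinibDistribution",
    "ParallelismProfile",
    "sinib_pmf",
    "same_direction_null",
    "observed_parallelism",
    "parallelism_ks_test",
]


@dataclass
class SinibDistribution:
    """Exact pmf of the number of lines with a same-direction significant hit."""

    pmf: np.ndarray  # index x = 0..L
    method: str
    up_probs: np.ndarray
    down_probs: np.ndarray

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if (self.pmf < -1e-15).any():
            raise ValueError("pmf has negative mass")
        self.pmf = np.clip(self.pmf, 0.0, None)
        if abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf must sum to 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.pmf))

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)


@dataclass
class ParallelismProfile:
    """Observed vs expected gene counts per number of concordant lines x.

    ``observed`` and ``expected`` are indexed by x = 0..L; expected counts
    are G times the null pmf. ``gene_x`` retains the per-gene x for every
    gene with x >= 1 (the sample the KS test is run on).
    """

    observed: np.ndarray
    expected: np.ndarray
    expected_prob: np.ndarray
    n_genes: int
    gene_x: pd.Series
    null: SinibDistribution

    def to_frame(self) -> pd.DataFrame:
        x = np.arange(1, len(self.observed))
        return pd.DataFrame(
            {
                "x": x,
                "observed": self.observed[1:].astype(int),
                "expected": self.expected[1:],
                "expected_rounded": np.rint(self.expected[1:]).astype(int),
                "expected_prob": self.expected_prob[1:],
            }
        )


def sinib_pmf(trials_and_probs: list[tuple[int, float]]) -> np.ndarray:
    """Exact pmf of a sum of independent Binomial(n_i, p_i) variables.

    Computed by iterated convolution of the component binomial pmfs; the
    result has length sum(n_i) + 1. With all n_i = 1 this is the
    Poisson-binomial distribution.
    """
    if len(trials_and_probs) == 0:
        raise ValueError("need at least one (n, p) component")
    pmf = np.array([1.0])
    for n, p in trials_and_probs:
        if int(n) != n or n < 1:
            raise ValueError(f"n must be a positive integer, got {n}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {p}")
        comp = stats.binom.pmf(np.arange(int(n) + 1), int(n), p)
        pmf = np.convolve(pmf, comp)
    # renormalize away accumulated convolution round-off
    return pmf / pmf.sum()


def _max_pmf_independent(pmf_a: np.ndarray, pmf_b: np.ndarray) -> np.ndarray:
    """pmf of max(A, B) for independent discrete A, B on 0..L."""
    la, lb = len(pmf_a), len(pmf_b)
    n = max(la, lb)
    fa = np.cumsum(np.pad(pmf_a, (0, n - la)))
    fb = np.cumsum(np.pad(pmf_b, (0, n - lb)))
    fmax = fa * fb
    return np.diff(fmax, prepend=0.0)


def same_direction_null(deg: DEGCallSet, method: str = "sinib_independent") -> SinibDistribution:
    """Null distribution of x = lines with a same-direction significant hit.

    Parameters are the per-line hit probabilities u_i/G and d_i/G from the
    DEG call set. ``sinib_independent`` treats the up- and down-line counts
    as independent Poisson-binomial sums; ``trinomial_exact`` runs an exact
    dynamic program in which up/down are mutually exclusive within a line.
    """
    lines = deg.lines
    if len(lines) < 1:
        raise ValueError("need at least one line")
    g = deg.n_genes
    pu = np.array([deg.u(ln) / g for ln in lines])
    pd_ = np.array([deg.d(ln) / g for ln in lines])
    if ((pu + pd_) > 1 + 1e-12).any():
        raise ValueError("u_i + d_i exceeds the gene total in some line")
    if method == "sinib_independent":
        up = sinib_pmf([(1, p) for p in pu])
        down = sinib_pmf([(1, p) for p in pd_])
        pmf = _max_pmf_independent(up, down)
    elif method == "trinomial_exact":
        pmf = _trinomial_max_pmf(pu, pd_)
    else:
        raise ValueError("method must be 'sinib_independent' or 'trinomial_exact'")
    return SinibDistribution(pmf, method, pu, pd_)


def _trinomial_max_pmf(pu: np.ndarray, pd_: np.ndarray) -> np.ndarray:
    """Exact pmf of max(n_up, n_down) via a joint DP over lines."""
    L = len(pu)
    joint = np.zeros((L + 1, L + 1))
    joint[0, 0] = 1.0
    for i in range(L):
        nxt = np.zeros_like(joint)
        rest = 1.0 - pu[i] - pd_[i]
        nxt += joint * rest
        nxt[1:, :] += joint[:-1, :] * pu[i]
        nxt[:, 1:] += joint[:, :-1] * pd_[i]
        joint = nxt
    pmf = np.zeros(L + 1)
    iu, idn = np.indices(joint.shape)
    np.add.at(pmf, np.maximum(iu, idn).ravel(), joint.ravel())
    return pmf


def observed_parallelism(
    fc: pd.DataFrame,
    deg: DEGCallSet,
    method: str = "sinib_independent",
    direction: str = "per_direction_max",
) -> ParallelismProfile:
    """Observed per-gene concordant-line counts with the matched null.

    For each gene, S_up = number of lines where it is up-significant and
    S_down the analog; by default x(g) = max(S_up, S_down). With
    ``direction="unanimous"`` a gene only scores when all of its
    significant calls agree in sign (x = 0 for mixed-direction genes).
    """
    validate_fold_change_table(fc)
    fc_lines = set(fc["line"].unique())
    if not set(deg.lines) <= fc_lines:
        raise ValueError("fold-change table does not cover all lines in the DEG call set")
    if direction not in ("per_direction_max", "unanimous"):
        raise ValueError("direction must be 'per_direction_max' or 'unanimous'")
    genes = fc["gene_id"].unique()
    s_up = pd.Series(0, index=pd.Index(genes, name="gene_id"))
    s_down = s_up.copy()
    for line in deg.lines:
        s_up.loc[list(deg.up_genes[line])] += 1
        s_down.loc[list(deg.down_genes[line])] += 1
    if direction == "per_direction_max":
        x = np.maximum(s_up, s_down)
    else:
        x = np.where((s_up > 0) & (s_down > 0), 0, s_up + s_down)
        x = pd.Series(x, index=s_up.index)
    null = same_direction_null(deg, method=method)
    L = len(deg.lines)
    observed = np.bincount(x, minlength=L + 1).astype(float)
    observed[0] = float(deg.n_genes - (observed[1:].sum()))
    expected = deg.n_genes * null.pmf
    gene_x = x[x >= 1].astype(int)
    return ParallelismProfile(observed, expected, null.pmf.copy(), deg.n_genes, gene_x, null)


def parallelism_ks_test(
    profile: ParallelismProfile,
    p_method: str = "monte_carlo",
    n_sim: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """One-sample KS test of observed x values against the expected null.

    The sample is the per-gene x restricted to x >= 1; the reference is the
    null pmf conditioned on x >= 1. On this small discrete support the KS
    statistic is the maximum CDF discrepancy over the support points.

    ``p_method="monte_carlo"`` (default) simulates the statistic's null
    distribution by drawing multinomial samples of the same size from the
    conditioned pmf, which keeps the test calibrated despite discreteness;
    ``"asymptotic"`` applies the standard continuous-sample Kolmogorov
    formula, which is conservative on discrete support.
    """
    n = int(profile.observed[1:].sum())
    if n == 0:
        raise ValueError("no observed genes with x >= 1")
    tail = profile.expected_prob[1:]
    tail_mass = tail.sum()
    if tail_mass <= 0:
        raise ValueError("null places no mass on x >= 1")
    p_cond = tail / tail_mass
    obs_counts = profile.observed[1:]
    ecdf = np.cumsum(obs_counts) / n
    cdf = np.cumsum(p_cond)
    d_obs = float(np.max(np.abs(ecdf - cdf)))
    if p_method == "asymptotic":
        p = float(special.kolmogorov(d_obs * np.sqrt(n)))
        logger.info("asymptotic KS on discrete support: p-value is conservative")
    elif p_method == "monte_carlo":
        rng = np.random.default_rng(rng)
        sims = rng.multinomial(n, p_cond, size=n_sim)
        sim_ecdf = np.cumsum(sims, axis=1) / n
        d_sim = np.max(np.abs(sim_ecdf - cdf), axis=1)
        p = (1.0 + np.sum(d_sim >= d_obs - 1e-12)) / (1.0 + n_sim)
    else:
        raise ValueError("p_method must be 'monte_carlo' or 'asymptotic'")
    return {"statistic": d_obs, "pvalue": float(p), "n": n, "p_method": p_method}


def parallelism_pipeline(
    fc: pd.DataFrame,
    q_threshold: float = 0.01,
    method: str = "sinib_independent",
    p_method: str = "monte_carlo",
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Convenience wrapper: DEG calls -> profile -> KS test in one call."""
    deg = call_degs(fc, q_threshold)
    profile = observed_parallelism(fc, deg, method=method)
    test = parallelism_ks_test(profile, p_method=p_method, rng=rng)
    return {"deg": deg, "profile": profile, "test": test}
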