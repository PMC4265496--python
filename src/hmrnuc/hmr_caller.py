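"""Hypomethylated-region (HMR) calling with a two-state HMM.

Per-CpG methylated/total read counts are modelled as a two-state hidden
Markov chain over CpG sites (states HYPO and METH) with beta-binomial
emissions, which absorb the overdispersion of bisulfite count data.
Parameters are fitted by Baum-Welch; the emission M-step uses weighted
moment matching, accepted only when it improves the expected
complete-data likelihood so the EM ascent property is preserved
(generalized EM). HMRs are maximal runs of CpGs whose posterior
probability of HYPO exceeds 0.5, with at least ``min_cpgs`` CpGs, split
across inter-CpG gaps larger than ``max_gap`` so unsequenced deserts do
not bridge separate regions.

Boundary conventions: an HMR boundary can be anchored at the first or
second unmethylated CpG inside the region, or at the adjacent
(methylated) CpG just outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numba import njit
from scipy.stats import betabinom

from .genomic_io import CpGRecord, GenomicInterval, ValidationError

HYPO, METH = 0, 1

BoundaryMode = Literal["first_unmeth", "second_unmeth", "adjacent_meth"]
Side = Literal["5prime", "3prime"]

_MODES = ("first_unmeth", "second_unmeth", "adjacent_meth")
_SIDES = ("5prime", "3prime")


@dataclass
class HmmParams:
    """Two-state HMM parameters with beta-binomial emissions.

    State 0 is HYPO, state 1 is METH; after fitting, states are relabeled
    so that the HYPO expected methylation level alpha/(alpha+beta) is the
    lower of the two.
    """

    pi: np.ndarray
    trans: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.pi.shape != (2,) or self.trans.shape != (2, 2):
            raise ValidationError("pi must be length 2 and trans 2x2")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValidationError("pi must sum to 1")
        if np.max(np.abs(self.trans.sum(axis=1) - 1.0)) > 1e-9:
            raise ValidationError("transition rows must sum to 1")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValidationError("beta-binomial alpha and beta must be > 0")

    @property
    def expected_levels(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)

    def relabeled(self) -> "HmmParams":
        """Return a copy with state 0 = lower expected level (HYPO)."""
        if self.expected_levels[0] <= self.expected_levels[1]:
            return self
        perm = [1, 0]
        return HmmParams(
            pi=self.pi[perm],
            trans=self.trans[np.ix_(perm, perm)],
            alpha=self.alpha[perm],
            beta=self.beta[perm],
        )


@dataclass
class HMRInterval:
    """A called hypomethylated region with its CpGs and boundary anchors."""

    interval: GenomicInterval
    cpg_positions: tuple[int, ...]
    mean_level: float
    boundary_5: dict[str, int | None] = field(default_factory=dict)
    boundary_3: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = self.cpg_positions
        if len(pos) < 1:
            raise ValidationError("HMR must contain at least one CpG")
        if any(b >= a for a, b in zip(pos[1:], pos[:-1])):
            raise ValidationError("HMR CpG positions must be strictly increasing")
        if not (self.interval.start <= pos[0] and pos[-1] < self.interval.end):
            raise ValidationError("HMR CpGs must lie within its interval")
        if not 0.0 <= self.mean_level <= 1.0:
            raise ValidationError("mean_level must be in [0, 1]")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class HmmFit:
    params: HmmParams
    log_likelihoods: list[float]
    converged: bool
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Scaled forward-backward (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_backward(e: np.ndarray, pi: np.ndarray, trans: np.ndarray):
    """Scaled forward-backward for 2 states.

    ``e`` holds per-site emission likelihoods rescaled so each row's max
    is 1; returns (gamma, xi_sum, log_scale_sum) where log_scale_sum must
    be combined with the per-row rescaling constants for the full
    log-likelihood.
    """
    n = e.shape[0]
    alpha = np.empty((n, 2))
    beta = np.empty((n, 2))
    c = np.empty(n)

    a0 = pi[0] * e[0, 0]
    a1 = pi[1] * e[0, 1]
    c[0] = a0 + a1
    alpha[0, 0] = a0 / c[0]
    alpha[0, 1] = a1 / c[0]
    for t in range(1, n):
        a0 = (alpha[t - 1, 0] * trans[0, 0] + alpha[t - 1, 1] * trans[1, 0]) * e[t, 0]
        a1 = (alpha[t - 1, 0] * trans[0, 1] + alpha[t - 1, 1] * trans[1, 1]) * e[t, 1]
        c[t] = a0 + a1
        alpha[t, 0] = a0 / c[t]
        alpha[t, 1] = a1 / c[t]

    beta[n - 1, 0] = 1.0
    beta[n - 1, 1] = 1.0
    for t in range(n - 2, -1, -1):
        b0 = (
            trans[0, 0] * e[t + 1, 0] * beta[t + 1, 0]
            + trans[0, 1] * e[t + 1, 1] * beta[t + 1, 1]
        )
        b1 = (
            trans[1, 0] * e[t + 1, 0] * beta[t + 1, 0]
            + trans[1, 1] * e[t + 1, 1] * beta[t + 1, 1]
        )
        beta[t, 0] = b0 / c[t + 1]
        beta[t, 1] = b1 / c[t + 1]

    gamma = np.empty((n, 2))
    for t in range(n):
        g0 = alpha[t, 0] * beta[t, 0]
        g1 = alpha[t, 1] * beta[t, 1]
        s = g0 + g1
        gamma[t, 0] = g0 / s
        gamma[t, 1] = g1 / s

    xi_sum = np.zeros((2, 2))
    for t in range(n - 1):
        denom = c[t + 1]
        for i in range(2):
            for j in range(2):
                xi_sum[i, j] += (
                    alpha[t, i] * trans[i, j] * e[t + 1, j] * beta[t + 1, j] / denom
                )

    log_scale = 0.0
    for t in range(n):
        log_scale += np.log(c[t])
    return gamma, xi_sum, log_scale


def _log_emissions(meth: np.ndarray, total: np.ndarray, params: HmmParams) -> np.ndarray:
    loge = np.empty((len(meth), 2))
    for s in range(2):
        loge[:, s] = betabinom.logpmf(meth, total, params.alpha[s], params.beta[s])
    return loge


def _fb_chrom(meth, total, params):
    loge = _log_emissions(meth, total, params)
    m = loge.max(axis=1)
    e = np.exp(loge - m[:, None])
    gamma, xi_sum, log_scale = _forward_backward(e, params.pi, params.trans)
    loglik = log_scale + m.sum()
    return gamma, xi_sum, loglik


def _group_by_chrom(cpgs: Sequence[CpGRecord]):
    """Split sorted CpG records into per-chromosome numpy arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chroms: dict[str, list[CpGRecord]] = {}
    for r in cpgs:
        chroms.setdefault(r.chrom, []).append(r)
    for chrom, recs in chroms.items():
        recs = sorted(recs, key=lambda r: r.pos)
        pos = np.array([r.pos for r in recs], dtype=np.int64)
        meth = np.array([r.meth_count for r in recs], dtype=np.int64)
        total = np.array([r.total_count for r in recs], dtype=np.int64)
        out[chrom] = (pos, meth, total)
    return out


# ---------------------------------------------------------------------------
# Baum-Welch fitting
# ---------------------------------------------------------------------------

def _moment_match_emission(
    meth: np.ndarray, total: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted beta-binomial moment matching on observed levels.

    The sample variance of levels mixes beta variance and binomial noise:
    Var(p_i) = mu(1-mu) * (rho + (1-rho) * E[1/n_i]); solving for rho
    gives the intra-class correlation, hence concentration (1-rho)/rho.
    """
    wsum = w.sum()
    if wsum <= 0:
        return 1.0, 1.0
    p = meth / total
    mu = float(np.dot(w, p) / wsum)
    mu = min(max(mu, 1e-4), 1 - 1e-4)
    v = float(np.dot(w, (p - mu) ** 2) / wsum)
    e_inv = float(np.dot(w, 1.0 / total) / wsum)
    denom = mu * (1 - mu)
    rho = (v / denom - e_inv) / (1 - e_inv) if denom > 0 else 0.1
    rho = min(max(rho, 1e-4), 0.9)
    conc = (1 - rho) / rho
    a = min(max(mu * conc, 1e-3), 1e4)
    b = min(max((1 - mu) * conc, 1e-3), 1e4)
    return a, b


def _emission_q(meth, total, w, a, b) -> float:
    return float(np.dot(w, betabinom.logpmf(meth, total, a, b)))


def fit_hmm(
    cpgs: Sequence[CpGRecord],
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> HmmFit:
    """Fit the two-state beta-binomial HMM by Baum-Welch.

    The log-likelihood is non-decreasing across iterations: transition and
    initial-state updates are exact M-steps, and each emission update is
    kept only if it improves its expected complete-data term.
    """
    data = _group_by_chrom(cpgs)
    if sum(len(v[0]) for v in data.values()) < 2:
        raise ValidationError("need at least 2 CpGs with reads to fit the HMM")

    rng = np.random.default_rng(seed)
    # Mild seeded jitter on a generic initialization; levels well apart.
    lo = 0.08 * (1 + 0.2 * rng.uniform(-1, 1))
    hi = 0.80 * (1 + 0.1 * rng.uniform(-1, 1))
    conc = 8.0
    params = HmmParams(
        pi=np.array([0.5, 0.5]),
        trans=np.array([[0.9, 0.1], [0.1, 0.9]]),
        alpha=np.array([lo * conc, hi * conc]),
        beta=np.array([(1 - lo) * conc, (1 - hi) * conc]),
    )

    warnings: list[str] = []
    logliks: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E-step
        total_ll = 0.0
        xi_acc = np.zeros((2, 2))
        gamma0_acc = np.zeros(2)
        gammas = {}
        for chrom, (pos, meth, total) in data.items():
            gamma, xi_sum, ll = _fb_chrom(meth, total, params)
            total_ll += ll
            xi_acc += xi_sum
            gamma0_acc += gamma[0]
            gammas[chrom] = gamma
        logliks.append(total_ll)
        if len(logliks) > 1 and abs(logliks[-1] - logliks[-2]) < tol:
            converged = True
            break

        # M-step: transitions / initial distribution (exact)
        trans = xi_acc / np.maximum(xi_acc.sum(axis=1, keepdims=True), 1e-300)
        trans = np.clip(trans, 1e-8, None)
        trans /= trans.sum(axis=1, keepdims=True)
        pi = gamma0_acc / gamma0_acc.sum()

        # M-step: emissions (moment matching, accepted only on improvement)
        meth_all = np.concatenate([v[1] for v in data.values()])
        total_all = np.concatenate([v[2] for v in data.values()])
        gamma_all = np.concatenate([gammas[c] for c in data.keys()])
        alpha_new = params.alpha.copy()
        beta_new = params.beta.copy()
        for s in range(2):
            w = gamma_all[:, s]
            a, b = _moment_match_emission(meth_all, total_all, w)
            q_new = _emission_q(meth_all, total_all, w, a, b)
            q_old = _emission_q(meth_all, total_all, w, params.alpha[s], params.beta[s])
            if q_new > q_old:
                alpha_new[s], beta_new[s] = a, b
        params = HmmParams(pi=pi, trans=trans, alpha=alpha_new, beta=beta_new)

    if not converged:
        warnings.append(f"Baum-Welch did not converge within {max_iter} iterations")
    levels = params.expected_levels
    if abs(levels[0] - levels[1]) < 1e-3:
        warnings.append("degenerate fit: the two states have near-identical levels")
    return HmmFit(
        params=params.relabeled(),
        log_likelihoods=logliks,
        converged=converged,
        warnings=warnings,
    )


def posterior_hypo(cpgs: Sequence[CpGRecord], params: HmmParams) -> dict[str, np.ndarray]:
    """Per-chromosome posterior P(state = HYPO) for each CpG, in position order."""
    out = {}
    for chrom, (pos, meth, total) in _group_by_chrom(cpgs).items():
        gamma, _, _ = _fb_chrom(meth, total, params)
        out[chrom] = gamma[:, HYPO]
    return out


# ---------------------------------------------------------------------------
# Decoding and boundaries
# ---------------------------------------------------------------------------

def decode_hmrs(
    cpgs: Sequence[CpGRecord],
    params: HmmParams,
    min_cpgs: int = 4,
    max_gap: int = 10_000,
) -> list[HMRInterval]:
    """Posterior-decode HMRs: maximal runs of CpGs with P(HYPO) > 0.5.

    Runs spanning an inter-CpG gap larger than ``max_gap`` are split; runs
    with fewer than ``min_cpgs`` CpGs are discarded. The interval spans
    the first to last HYPO CpG + 1.
    """
    hmrs: list[HMRInterval] = []
    grouped = _group_by_chrom(cpgs)
    for chrom in sorted(grouped):
        pos, meth, total = grouped[chrom]
        gamma, _, _ = _fb_chrom(meth, total, params)
        hypo = gamma[:, HYPO] > 0.5
        runs: list[list[int]] = []
        current: list[int] = []
        for i in range(len(pos)):
            if not hypo[i]:
                if current:
                    runs.append(current)
                    current = []
                continue
            if current and pos[i] - pos[current[-1]] > max_gap:
                runs.append(current)
                current = []
            current.append(i)
        if current:
            runs.append(current)
        for run in runs:
            if len(run) < min_cpgs:
                continue
            idx = np.array(run)
            run_pos = tuple(int(p) for p in pos[idx])
            levels = meth[idx] / total[idx]
            hmr = HMRInterval(
                interval=GenomicInterval(chrom, run_pos[0], run_pos[-1] + 1),
                cpg_positions=run_pos,
                mean_level=float(levels.mean()),
            )
            for side in _SIDES:
                target = hmr.boundary_5 if side == "5prime" else hmr.boundary_3
                for mode in _MODES:
                    target[mode] = extract_boundary(hmr, pos, mode, side)
            hmrs.append(hmr)
    return hmrs


def extract_boundary(
    hmr: HMRInterval,
    all_cpg_positions: Sequence[int] | np.ndarray,
    mode: BoundaryMode,
    side: Side,
) -> int | None:
    """Boundary anchor position under one of the three conventions.

    first_unmeth: the outermost CpG of the HMR on the given side;
    second_unmeth: the next CpG inward; adjacent_meth: the nearest CpG
    outside the HMR on that side. None when no such CpG exists.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown boundary mode {mode!r}")
    if side not in _SIDES:
        raise ValueError(f"unknown side {side!r}")
    pos = np.asarray(all_cpg_positions, dtype=np.int64)
    first = hmr.cpg_positions[0] if side == "5prime" else hmr.cpg_positions[-1]
    if mode == "first_unmeth":
        return int(first)
    if mode == "second_unmeth":
        if hmr.n_cpgs < 2:
            return None
        return int(hmr.cpg_positions[1] if side == "5prime" else hmr.cpg_positions[-2])
    # adjacent_meth
    if side == "5prime":
        i = np.searchsorted(pos, hmr.cpg_positions[0], side="left") - 1
        return int(pos[i]) if i >= 0 else None
    i = np.searchsorted(pos, hmr.cpg_positions[-1], side="right")
    return int(pos[i]) if i < len(pos) else None


@dataclass
class GapStats:
    """Distance from the first unmethylated CpG to the adjacent methylated CpG."""

    n: int
    mean: float
    median: float
    gaps_5prime: np.ndarray
    gaps_3prime: np.ndarray
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray


def boundary_gap_stats(hmrs: Sequence[HMRInterval], bin_width: int = 25) -> GapStats:
    """Summarize first_unmeth -> adjacent_meth distances over both sides."""
    g5, g3 = [], []
    for hmr in hmrs:
        f5, a5 = hmr.boundary_5.get("first_unmeth"), hmr.boundary_5.get("adjacent_meth")
        f3, a3 = hmr.boundary_3.get("first_unmeth"), hmr.boundary_3.get("adjacent_meth")
        if f5 is not None and a5 is not None:
            g5.append(f5 - a5)
        if f3 is not None and a3 is not None:
            g3.append(a3 - f3)
    g5a = np.array(g5, dtype=float)
    g3a = np.array(g3, dtype=float)
    allg = np.concatenate([g5a, g3a])
    if len(allg) == 0:
        return GapStats(0, float("nan"), float("nan"), g5a, g3a, np.array([]), np.array([]))
    edges = np.arange(0, allg.max() + bin_width, bin_width)
    counts, edges = np.histogram(allg, bins=edges if len(edges) > 1 else 10)
    return GapStats(
        n=len(allg),
        mean=float(allg.mean()),
        median=float(np.median(allg)),
        gaps_5prime=g5a,
        gaps_3prime=g3a,
        histogram_edges=edges,
        histogram_counts=counts,
    )


def call_hmrs(
    cpgs: Sequence[CpGRecord],
    min_cpgs: int = 4,
    max_gap: int = 10_000,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[list[HMRInterval], HmmFit]:
    """Fit the HMM and decode HMRs in one call."""
    fit = fit_hmm(cpgs, max_iter=max_iter, tol=tol, seed=seed)
    hmrs = decode_hmrs(cpgs, fit.params, min_cpgs=min_cpgs, max_gap=max_gap)
    return hmrs, fit
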