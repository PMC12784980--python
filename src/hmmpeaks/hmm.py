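"""Constrained three-state HMM (zero / noise / signal) with negative-binomial
emissions, fitted genome-wide by Baum-Welch with post-iteration constraint
projection, plus per-bin posterior error probabilities (PEP).

States are indexed ZERO=0, NOISE=1, SIGNAL=2.  The zero state is a point
mass at count 0; noise and signal are negative binomial with parameters
(mean, failures r), variance = mean + mean^2 / r.  All chromosomes are
independent observation sequences sharing a single parameter set.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import nbinom

from .preprocess import BinnedTrack

logger = logging.getLogger(__name__)

ZERO, NOISE, SIGNAL = 0, 1, 2
STATE_NAMES = ("zero", "noise", "signal")

_MAX_FAILURES = 1e6
_MIN_FAILURES = 1e-3


class EmptySignalError(ValueError):
    """All counts are zero; nothing to fit."""


@dataclass
class NegBinParams:
    mean: float
    failures: float  # dispersion r > 0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be > 0")
        if self.failures <= 0:
            raise ValueError("failures must be > 0")

    @property
    def p(self) -> float:
        """Success probability of the scipy parameterization."""
        return self.failures / (self.failures + self.mean)

    def logpmf(self, counts: np.ndarray) -> np.ndarray:
        return nbinom.logpmf(counts, self.failures, self.p)


@dataclass
class Constraints:
    snr_min: float = 20.0
    noise_min: float = 0.01
    max_iterations: int = 20
    tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if self.snr_min <= 1:
            raise ValueError("snr_min must be > 1")
        if self.noise_min <= 0:
            raise ValueError("noise_min must be > 0")


@dataclass
class HmmModel:
    initial: np.ndarray  # (3,)
    transitions: np.ndarray  # (3, 3) row-stochastic
    noise: NegBinParams
    signal: NegBinParams
    log_likelihood_trace: list[float] = field(default_factory=list)
    projection_trace: list[bool] = field(default_factory=list)

    def validate(self) -> None:
        if not np.allclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probabilities do not sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows do not sum to 1")

    def emission_log_matrix(self, counts: np.ndarray) -> np.ndarray:
        """(n, 3) log emission probabilities for integer counts."""
        counts = np.asarray(counts)
        uniq, inv = np.unique(counts, return_inverse=True)
        out = np.empty((len(counts), 3))
        out[:, ZERO] = np.where(counts == 0, 0.0, -np.inf)
        out[:, NOISE] = self.noise.logpmf(uniq)[inv]
        out[:, SIGNAL] = self.signal.logpmf(uniq)[inv]
        return out


@dataclass
class PosteriorTrack:
    """Per-chromosome per-bin state posteriors and PEPs."""

    posteriors: dict[str, np.ndarray]  # (n, 3) rows summing to 1
    pep: dict[str, np.ndarray] = field(default_factory=dict)

    def concat_pep(self) -> np.ndarray:
        return np.concatenate(list(self.pep.values()))


def emission_logprob(state, count: int, model: HmmModel) -> float:
    """Log emission probability of one count under one state.

    ``state`` may be an index or one of "zero"/"noise"/"signal".
    """
    if isinstance(state, str):
        state = STATE_NAMES.index(state)
    if count < 0:
        raise ValueError("count must be non-negative")
    if state == ZERO:
        return 0.0 if count == 0 else -math.inf
    params = model.noise if state == NOISE else model.signal
    return float(params.logpmf(np.array([count]))[0])


def _moments_to_nb(values: np.ndarray) -> NegBinParams:
    m = float(values.mean())
    v = float(values.var())
    m = max(m, 1e-6)
    if v > m:
        r = m * m / (v - m)
    else:
        r = _MAX_FAILURES
    return NegBinParams(m, float(np.clip(r, _MIN_FAILURES, _MAX_FAILURES)))


def _project(
    model: HmmModel,
    constraints: Constraints,
    signal_cap: Optional[float] = None,
    lower_noise: bool = False,
) -> bool:
    """Enforce the data-dependent boundaries on the state parameters.

    Noise floor, minimal SNR, and the noise/signal swap guard.  Raising the
    signal mean to satisfy the SNR bound can push it beyond the data range
    (``signal_cap``, the maximum observed count), making the state unable to
    emit anything; the signal mean is then clamped to the cap.  When
    ``lower_noise`` is set (zero state dominates the background, so the
    noise state is not modeling genuine background coverage) the noise mean
    is additionally lowered to restore the SNR bound under the cap.
    Returns True if any adjustment fired.
    """
    fired = False
    if model.noise.mean < constraints.noise_min:
        model.noise = NegBinParams(constraints.noise_min, model.noise.failures)
        fired = True
    if model.signal.mean / model.noise.mean < constraints.snr_min:
        model.signal = NegBinParams(constraints.snr_min * model.noise.mean, model.signal.failures)
        fired = True
    if signal_cap is not None and model.signal.mean > signal_cap > 0:
        model.signal = NegBinParams(signal_cap, model.signal.failures)
        if lower_noise:
            noise_mean = max(min(model.noise.mean, signal_cap / constraints.snr_min), 1e-6)
            model.noise = NegBinParams(noise_mean, model.noise.failures)
        fired = True
    if model.signal.mean < model.noise.mean:  # state-swap guard
        model.noise, model.signal = model.signal, model.noise
        perm = [ZERO, SIGNAL, NOISE]
        model.transitions = model.transitions[np.ix_(perm, perm)]
        model.initial = model.initial[perm]
        fired = True
    return fired


def initialize_model(track: BinnedTrack, constraints: Constraints) -> HmmModel:
    """Method-of-moments initialization from the binned counts.

    Nonzero counts are split at their 95th percentile into noise/signal
    populations; the split point is then refined by alternating moment
    reassignment (threshold at the geometric mean of the two state means)
    until stable.  Transitions start diagonally dominant, the initial vector
    from observed occupancies, and the constraints are projected once.
    """
    counts = np.concatenate([np.asarray(c) for c in track.counts.values()])
    nz = counts[counts > 0]
    if len(nz) == 0:
        raise EmptySignalError("empty signal: all counts are zero")
    if len(nz) < 1000:
        logger.warning("only %d nonzero bins; initialization may be unstable", len(nz))

    q95 = np.quantile(nz, 0.95)
    lower = nz[nz <= q95]
    upper = nz[nz > q95]
    if len(upper) == 0:
        upper = nz[nz >= q95]
    noise = _moments_to_nb(lower)
    signal = _moments_to_nb(upper)

    # refine the split: the quantile cut misassigns signal bins when the
    # signal fraction exceeds 5% of nonzero bins
    for _ in range(10):
        thr = math.sqrt(noise.mean * max(signal.mean, noise.mean))
        lo, hi = nz[nz < thr], nz[nz >= thr]
        if len(lo) == 0 or len(hi) == 0:
            break
        new_noise, new_signal = _moments_to_nb(lo), _moments_to_nb(hi)
        converged = (
            abs(new_noise.mean - noise.mean) < 1e-9 and abs(new_signal.mean - signal.mean) < 1e-9
        )
        noise, signal = new_noise, new_signal
        if converged:
            break
    thr = math.sqrt(noise.mean * max(signal.mean, noise.mean))
    n_lower = int((nz < thr).sum()) or len(lower)
    n_upper = max(len(nz) - n_lower, 1)

    n_zero = len(counts) - len(nz)
    occ = np.array([n_zero, n_lower, n_upper], dtype=float)
    occ = np.maximum(occ, 1.0)
    initial = occ / occ.sum()
    transitions = np.full((3, 3), 0.01)
    np.fill_diagonal(transitions, 0.98)
    model = HmmModel(initial=initial, transitions=transitions, noise=noise, signal=signal)
    zero_dominated = n_zero / len(counts) > 0.5
    _project(model, constraints, signal_cap=float(counts.max()), lower_noise=zero_dominated)
    model.validate()
    return model


def _chrom_forward_backward(counts: np.ndarray, model: HmmModel, chrom: str):
    """Scaled forward-backward for one chromosome.

    Returns (gamma, xi_sum, first_gamma, log_likelihood).  Emission rows are
    rescaled by their maximum in log space so that scaling never underflows;
    the subtracted constants are added back into the log-likelihood.
    """
    logB = model.emission_log_matrix(counts)
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])
    A = model.transitions
    n = len(counts)
    alpha = np.empty((n, 3))
    c = np.empty(n)
    a = model.initial * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise ValueError(f"model cannot emit data at {chrom} bin 0")
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ A) * B[t]
        ct = a.sum()
        if ct <= 0:
            raise ValueError(f"model cannot emit data at {chrom} bin {t}")
        c[t] = ct
        alpha[t] = a / ct
    beta = np.empty((n, 3))
    beta[n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if n > 1:
        xi_sum = A * (alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None]))
    else:
        xi_sum = np.zeros((3, 3))
    loglik = float(np.log(c).sum() + m.sum())
    return gamma, xi_sum, gamma[0].copy(), loglik


def forward_backward(track: BinnedTrack, model: HmmModel):
    """Posterior state probabilities and total log-likelihood.

    Each chromosome is an independent sequence restarting from the initial
    distribution.  Returns ``(PosteriorTrack, loglik)``; the PEP fields are
    filled via :func:`compute_pep`.
    """
    pt, loglik, _, _ = _e_step(track, model)
    return compute_pep(pt), loglik


def _e_step(track: BinnedTrack, model: HmmModel):
    model.validate()
    posteriors: dict[str, np.ndarray] = {}
    xi_total = np.zeros((3, 3))
    firsts = []
    loglik = 0.0
    for chrom, counts in track.counts.items():
        counts = np.asarray(counts, dtype=np.int64)
        gamma, xi_sum, first, ll = _chrom_forward_backward(counts, model, chrom)
        posteriors[chrom] = gamma
        xi_total += xi_sum
        firsts.append(first)
        loglik += ll
    return PosteriorTrack(posteriors), loglik, xi_total, np.array(firsts)


def compute_pep(posteriors: PosteriorTrack) -> PosteriorTrack:
    """PEP per bin = posterior(zero) + posterior(noise) = 1 - posterior(signal)."""
    for chrom, gamma in posteriors.posteriors.items():
        posteriors.pep[chrom] = gamma[:, ZERO] + gamma[:, NOISE]
    return posteriors


def fit_constrained(track: BinnedTrack, constraints: Constraints, seed: int = 0) -> HmmModel:
    """Constrained Baum-Welch fit.

    Initialization is deterministic (``seed`` is accepted for interface
    symmetry but unused).  After each M-step the constraints are projected:
    noise floor, minimal SNR, and the noise/signal swap guard.  Stops when
    the relative log-likelihood change falls below ``tolerance`` or after
    ``max_iterations``.  A likelihood decrease following a projection-free
    iteration raises, since plain EM is monotone.
    """
    model = initialize_model(track, constraints)
    counts_all = np.concatenate([np.asarray(c, dtype=np.int64) for c in track.counts.values()])
    signal_cap = float(counts_all.max())
    zero_dominated = bool((counts_all == 0).mean() > 0.5)
    prev_ll: Optional[float] = None
    prev_projection_free = False
    for _ in range(constraints.max_iterations):
        pt, ll, xi_total, firsts = _e_step(track, model)
        model.log_likelihood_trace.append(ll)
        if prev_ll is not None:
            if prev_projection_free and ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
                raise RuntimeError(
                    f"EM monotonicity violated: {prev_ll} -> {ll} without projection"
                )
            if abs(ll - prev_ll) / max(abs(prev_ll), 1.0) < constraints.tolerance:
                break
        prev_ll = ll

        # M-step
        initial = firsts.mean(axis=0)
        initial = np.maximum(initial, 1e-12)
        model.initial = initial / initial.sum()
        row_sums = xi_total.sum(axis=1, keepdims=True)
        new_A = model.transitions.copy()
        ok = row_sums[:, 0] > 0
        new_A[ok] = xi_total[ok] / row_sums[ok]
        model.transitions = new_A

        gamma_all = np.concatenate([g for g in pt.posteriors.values()])
        for state in (NOISE, SIGNAL):
            w = gamma_all[:, state]
            wsum = w.sum()
            if wsum <= 1e-10:
                continue
            mu = max(float((w * counts_all).sum() / wsum), 1e-6)
            var = float((w * (counts_all - mu) ** 2).sum() / wsum)
            r = mu * mu / (var - mu) if var > mu else _MAX_FAILURES
            params = NegBinParams(mu, float(np.clip(r, _MIN_FAILURES, _MAX_FAILURES)))
            if state == NOISE:
                model.noise = params
            else:
                model.signal = params

        fired = _project(
            model, constraints, signal_cap=signal_cap, lower_noise=zero_dominated
        )
        model.projection_trace.append(fired)
        prev_projection_free = not fired

    assert model.noise.mean >= constraints.noise_min - 1e-12
    snr = model.signal.mean / model.noise.mean
    if snr < constraints.snr_min - 1e-9:
        # SNR bound unattainable within the data range: signal sits at the cap
        assert abs(model.signal.mean - signal_cap) <= 1e-6 * max(signal_cap, 1.0)
        logger.info(
            "SNR bound %.1f unattainable within data range (signal capped at %.1f, snr %.2f)",
            constraints.snr_min, signal_cap, snr,
        )
    return model


# ---------------------------------------------------------------------------
# model persistence: tab-delimited single-file dump

def save_model(model: HmmModel, constraints: Constraints, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("initial\t" + "\t".join(repr(float(x)) for x in model.initial) + "\n")
        for i in range(3):
            fh.write(
                f"transitions_{i}\t" + "\t".join(repr(float(x)) for x in model.transitions[i]) + "\n"
            )
        fh.write(f"noise\t{model.noise.mean!r}\t{model.noise.failures!r}\n")
        fh.write(f"signal\t{model.signal.mean!r}\t{model.signal.failures!r}\n")
        fh.write(
            f"constraints\t{constraints.snr_min!r}\t{constraints.noise_min!r}"
            f"\t{constraints.max_iterations}\t{constraints.tolerance!r}\n"
        )
        fh.write("trace\t" + "\t".join(repr(float(x)) for x in model.log_likelihood_trace) + "\n")
        fh.write("projections\t" + "\t".join(str(int(x)) for x in model.projection_trace) + "\n")


def load_model(path: str) -> tuple[HmmModel, Constraints]:
    rows: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows[fields[0]] = fields[1:]
    initial = np.array([float(x) for x in rows["initial"]])
    transitions = np.array([[float(x) for x in rows[f"transitions_{i}"]] for i in range(3)])
    noise = NegBinParams(float(rows["noise"][0]), float(rows["noise"][1]))
    signal = NegBinParams(float(rows["signal"][0]), float(rows["signal"][1]))
    c = rows["constraints"]
    constraints = Constraints(float(c[0]), float(c[1]), int(c[2]), float(c[3]))
    trace = [float(x) for x in rows.get("trace", []) if x]
    projections = [bool(int(x)) for x in rows.get("projections", []) if x]
    model = HmmModel(initial, transitions, noise, signal, trace, projections)
    model.validate()
    return model, constraints
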