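"""Convergence diagnostics for MCMC output: autocorrelation, effective
sample size, and the split-chain scale-reduction statistic.

Random-walk Metropolis chains on this model mix slowly (strong
autocorrelation), so every fit should be checked: the effective sample
size quantifies how much thinning or chain extension buys, and split-R-hat
compares parallel (or split) chains.  Flag thresholds — ESS below 100 or
split-R-hat above 1.05 — are package policy defaults, configurable at the
report level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "autocorrelation",
    "effective_sample_size",
    "split_rhat",
    "DiagnosticsReport",
    "diagnose",
]

ESS_FLAG_THRESHOLD = 100.0
RHAT_FLAG_THRESHOLD = 1.05


def autocorrelation(chain: np.ndarray, max_lag: int = 100) -> np.ndarray:
    """Autocorrelation at lags 0..max_lag (biased autocovariance estimator
    normalized by lag 0, FFT-accelerated).

    A constant chain has undefined autocorrelation: lag 0 is returned as 1
    and later lags as NaN, with a warning.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ParameterError(f"max_lag must be < chain length, got {max_lag} >= {n}")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0.0:
        warnings.warn("autocorrelation of a constant chain is undefined", stacklevel=2)
        out = np.full(max_lag + 1, np.nan)
        out[0] = 1.0
        return out
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov / var


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS = n / (1 + 2 * sum rho_k), truncated by Geyer's initial positive
    sequence (consecutive lag-pair sums must stay positive).

    Degenerate (constant) chains are flagged and return 0.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 4:
        raise ParameterError(f"chain too short for an ESS estimate (length {n})")
    if np.ptp(x) == 0.0:
        warnings.warn("ESS of a constant chain is undefined; returning 0", stacklevel=2)
        return 0.0
    rho = autocorrelation(x, max_lag=n - 1)
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0.0:
            break
        s += pair
        k += 2
    return float(n / (1.0 + 2.0 * s))


def split_rhat(chains) -> float:
    """Split-chain potential scale reduction factor.

    Accepts a 2-D array (chains x draws) or a list of 1-D chains; a single
    chain is split in half.  Chains of unequal length are trimmed to the
    shortest with a warning.
    """
    if isinstance(chains, np.ndarray) and chains.ndim == 1:
        chains = [chains]
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) == 1:
        c = chains[0]
        half = len(c) // 2
        chains = [c[:half], c[half : 2 * half]]
    lengths = {len(c) for c in chains}
    if len(lengths) > 1:
        m = min(lengths)
        warnings.warn(
            f"chains of unequal length; trimming all to {m} draws", stacklevel=2
        )
        chains = [c[:m] for c in chains]
    # split every chain in half so within-chain drift also registers
    halves = []
    for c in chains:
        half = len(c) // 2
        halves.extend([c[:half], c[half : 2 * half]])
    arr = np.asarray(halves)
    m, n = arr.shape
    if n < 2:
        raise ParameterError("chains too short for split R-hat")
    means = arr.mean(axis=1)
    B = n * np.var(means, ddof=1)
    W = np.mean(np.var(arr, axis=1, ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence summary with warning flags."""

    ess: dict
    autocorrelations: dict
    rhat: dict
    acceptance_rates: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ess": self.ess,
            "autocorrelations": {k: list(v) for k, v in self.autocorrelations.items()},
            "split_rhat": self.rhat,
            "acceptance_rates": self.acceptance_rates,
            "flags": self.flags,
        }


def diagnose(
    chains_by_param: dict,
    acceptance_rates: dict | None = None,
    max_lag: int = 100,
    ess_threshold: float = ESS_FLAG_THRESHOLD,
    rhat_threshold: float = RHAT_FLAG_THRESHOLD,
) -> DiagnosticsReport:
    """Build a report from ``{parameter: chain or list of chains}``."""
    ess, acfs, rhats, flags = {}, {}, {}, []
    for name, chains in chains_by_param.items():
        if isinstance(chains, np.ndarray) and chains.ndim == 1:
            chains = [chains]
        pooled = np.concatenate(chains)
        lag = min(max_lag, len(pooled) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acfs[name] = autocorrelation(pooled, lag)
            ess[name] = float(sum(effective_sample_size(c) for c in chains))
            rhats[name] = split_rhat(chains)
        if ess[name] < ess_threshold:
            flags.append(f"{name}: ESS {ess[name]:.1f} < {ess_threshold:g}")
        if rhats[name] > rhat_threshold:
            flags.append(f"{name}: split R-hat {rhats[name]:.3f} > {rhat_threshold:g}")
    return DiagnosticsReport(
        ess=ess,
        autocorrelations=acfs,
        rhat=rhats,
        acceptance_rates=acceptance_rates or {},
        flags=flags,
    )


def plot_traces(chains_by_param: dict, outdir) -> list:
    """Render trace and autocorrelation plots to PNG files (one per
    parameter).  Plots are a reporting convenience; all assertions in the
    test suite are numeric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, chains in chains_by_param.items():
        if isinstance(chains, np.ndarray) and chains.ndim == 1:
            chains = [chains]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3))
        for c in chains:
            ax1.plot(np.asarray(c), lw=0.5)
        ax1.set_title(f"trace: {name}")
        pooled = np.concatenate(chains)
        lag = min(100, len(pooled) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acf = autocorrelation(pooled, lag)
        ax2.bar(np.arange(lag + 1), acf, width=1.0)
        ax2.set_title("autocorrelation")
        fig.tight_layout()
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
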