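"""Flow-cytometry compensation, log-ratio normalization, mixture gating and summaries.

Observed channel intensities are a linear mix of the true fluorophore signals
(spectral spillover); compensation inverts the spillover matrix. Per-event RFP is
normalized by GFP as log_e(RFP/GFP), and the doxycycline-induced subpopulation is
isolated with a two-component normal mixture fit by expectation-maximization —
cells that did not respond to induction form the low-ratio component and are
dropped. Condition summaries express induced-cell RFP as percent of the control
condition and compare conditions by one-way ANOVA with linear contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist
from sklearn.cluster import KMeans

__all__ = [
    "CHANNELS",
    "SpilloverMatrix",
    "MixtureFit",
    "PopulationSummary",
    "FlowConditionSummary",
    "compensate_events",
    "log_ratio_normalize",
    "fit_induced_mixture",
    "condition_summary_anova",
]

#: Detector channels in the contract order used by event tables and spillover rows.
CHANNELS = ("RFP", "GFP", "APC")


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover matrix: rows = fluorophores, columns = detectors.

    Entry [f, d] is the fraction of fluorophore f's signal read by detector d;
    the diagonal is 1. Observed = true @ matrix, so compensation multiplies by
    the inverse.
    """

    matrix: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ValueError(f"spillover matrix must be {k}x{k} for channels {self.channels}")
        if np.any(m < 0):
            raise ValueError("spillover entries must be non-negative")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal must be 1 (unit self-detection)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("spillover matrix is singular; cannot compensate")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, channels: tuple[str, ...] = CHANNELS) -> "SpilloverMatrix":
        return cls(np.eye(len(channels)), channels)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def compensate_events(events: pd.DataFrame, spillover: SpilloverMatrix) -> pd.DataFrame:
    """Undo spectral spillover: estimated true signals = observed @ inverse(spillover).

    Negative compensated values are preserved (not clipped); the log-ratio stage
    excludes non-positive events explicitly.
    """
    missing = [c for c in spillover.channels if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks channels {missing}")
    out = events.copy()
    observed = events.loc[:, list(spillover.channels)].to_numpy(dtype=float)
    out.loc[:, list(spillover.channels)] = observed @ spillover.inverse
    return out


def log_ratio_normalize(events: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Per-event log_e(RFP/GFP), excluding events with non-positive RFP or GFP.

    Returns the log-ratios of the surviving events and an exclusion log with the
    counts per reason. Raises if no event survives.
    """
    rfp = events["RFP"].to_numpy(dtype=float)
    gfp = events["GFP"].to_numpy(dtype=float)
    bad_rfp = rfp <= 0
    bad_gfp = gfp <= 0
    keep = ~(bad_rfp | bad_gfp)
    log = {
        "n_total": int(len(events)),
        "n_kept": int(keep.sum()),
        "n_nonpositive_rfp": int(bad_rfp.sum()),
        "n_nonpositive_gfp": int(bad_gfp.sum()),
    }
    if log["n_kept"] == 0:
        raise ValueError("no events with positive RFP and GFP after compensation")
    return np.log(rfp[keep] / gfp[keep]), log


@dataclass
class MixtureFit:
    """Two-component normal mixture of log_e(RFP/GFP) with induced assignment.

    The induced component is the one with the larger mean (deterministic under
    relabeling). ``degenerate`` marks effectively single-component data, in which
    case every event is assigned to that single component.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    induced_index: int
    responsibilities: np.ndarray
    induced_labels: np.ndarray
    converged: bool
    degenerate: bool
    log_likelihood: float
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


def _em_run(x, w, mu, var, tol, max_iter, var_floor):
    """One EM run from the given start; log-likelihood is checked to be monotone."""
    n = len(x)
    trace = []
    ll_prev = -np.inf
    converged = False
    xx = x[:, None]
    for it in range(max_iter):
        log_pdf = (
            -0.5 * np.log(2 * np.pi * var)[None, :]
            - (xx - mu[None, :]) ** 2 / (2 * var)[None, :]
        )
        weighted = np.log(w)[None, :] + log_pdf
        norm_c = logsumexp(weighted, axis=1)
        ll = float(norm_c.sum())
        if ll < ll_prev - 1e-8:
            raise RuntimeError(f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}")
        trace.append(ll)
        resp = np.exp(weighted - norm_c[:, None])
        if ll - ll_prev < tol and it > 0:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * xx).sum(axis=0) / nk
        var = (resp * (xx - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
    return w, mu, var, resp, ll_prev, trace, converged


def fit_induced_mixture(
    logratios,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a two-component normal mixture to per-event log-ratios.

    Initialization is by k-means on the 1-D data; ``n_restarts`` seeded restarts
    are run and the fit with the highest log-likelihood kept. Requires >= 50
    events. Data that are effectively one component — minor weight < 0.01, mean
    separation < 0.1 pooled SD, or a single-normal fit preferred by BIC (on
    unimodal data EM splits the sample into two overlapping halves, which the
    separation rule alone cannot catch) — are flagged degenerate; gating then
    passes every event through (there is no non-responder population to drop).
    """
    x = np.asarray(logratios, dtype=float)
    if x.ndim != 1 or len(x) < 50:
        raise ValueError(f"need at least 50 events to fit the mixture, got {len(x)}")
    var_floor = max(float(np.var(x)), 1e-12) * 1e-8 + 1e-300

    if np.ptp(x) == 0:  # all identical: nothing to separate
        n = len(x)
        return MixtureFit(
            weights=np.array([1.0, 0.0]),
            means=np.array([x[0], x[0]]),
            variances=np.array([var_floor, var_floor]),
            induced_index=0,
            responsibilities=np.column_stack([np.ones(n), np.zeros(n)]),
            induced_labels=np.ones(n, dtype=bool),
            converged=True,
            degenerate=True,
            log_likelihood=float("nan"),
        )

    rng = np.random.default_rng(seed)
    best = None
    errors = []
    for _ in range(n_restarts):
        km_seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=2, n_init=1, random_state=km_seed).fit(x[:, None])
        mu0 = km.cluster_centers_.ravel().astype(float)
        w0 = np.bincount(km.labels_, minlength=2).astype(float)
        w0 = np.maximum(w0, 1.0)
        w0 /= w0.sum()
        var0 = np.array([
            max(float(np.var(x[km.labels_ == k])) if np.any(km.labels_ == k) else np.var(x),
                var_floor)
            for k in range(2)
        ])
        try:
            res = _em_run(x, w0, mu0, var0, tol, max_iter, var_floor)
        except (RuntimeError, FloatingPointError) as exc:
            errors.append(str(exc))
            continue
        if best is None or res[4] > best[4]:
            best = res
    if best is None:
        raise RuntimeError(
            f"EM failed to converge in all {n_restarts} restarts; diagnostics: {errors}"
        )
    w, mu, var, resp, ll, trace, converged = best

    induced = int(np.argmax(mu))
    pooled_sd = math.sqrt(float(w @ var))
    # BIC comparison against a single normal: 2 free params vs 5
    n = len(x)
    ll_one = float(np.sum(
        -0.5 * np.log(2 * np.pi * np.var(x)) - (x - np.mean(x)) ** 2 / (2 * np.var(x))))
    bic_two = -2 * ll + 5 * math.log(n)
    bic_one = -2 * ll_one + 2 * math.log(n)
    degenerate = bool(
        min(w) < 0.01
        or abs(mu[1] - mu[0]) < 0.1 * pooled_sd
        or bic_one <= bic_two
    )
    if degenerate:
        labels = np.ones(n, dtype=bool)
    else:
        labels = resp[:, induced] >= 0.5
    return MixtureFit(
        weights=w, means=mu, variances=var, induced_index=induced,
        responsibilities=resp, induced_labels=labels, converged=converged,
        degenerate=degenerate, log_likelihood=ll, log_likelihood_trace=trace,
        n_iter=len(trace),
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Induced-cell summary of one experimentally independent cell population."""

    condition: str
    population: str
    mean_logratio: float
    mean_ratio: float  # arithmetic mean of RFP/GFP over induced events
    n_events: int


@dataclass
class FlowConditionSummary:
    """Per-condition percent-of-control table plus ANOVA / contrast statistics."""

    table: pd.DataFrame
    anova_f: float
    anova_p: float
    contrast_results: list[dict] = field(default_factory=list)


def summarize_population(
    condition: str, population: str, logratios, labels
) -> PopulationSummary:
    """Collapse one population's induced events to a :class:`PopulationSummary`."""
    lr = np.asarray(logratios, dtype=float)[np.asarray(labels, dtype=bool)]
    if len(lr) == 0:
        raise ValueError(f"{condition}/{population}: no induced events")
    return PopulationSummary(
        condition=condition, population=population,
        mean_logratio=float(np.mean(lr)), mean_ratio=float(np.mean(np.exp(lr))),
        n_events=int(len(lr)),
    )


def condition_summary_anova(
    populations: list[PopulationSummary],
    control: str = "control",
    contrasts: dict[str, dict[str, float]] | None = None,
    scale: str = "geometric",
) -> FlowConditionSummary:
    """Percent-of-control condition summary with one-way ANOVA and contrasts.

    Each population contributes one value: on the default geometric scale the
    back-transformed mean log-ratio exp(mean_logratio); on the arithmetic scale
    the mean per-event ratio. Condition means are expressed as percent of the
    control condition (control = 100%). The ANOVA and the contrasts are computed
    on log-scale per-population values (variance-stabilized), with contrast
    t-statistics using the pooled residual mean square.

    ``contrasts`` maps a contrast name to {condition: coefficient} with zero-sum
    coefficients. Conditions with fewer than 2 populations are excluded with a
    warning.
    """
    if scale not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown scale {scale!r}")
    by_cond: dict[str, list[PopulationSummary]] = {}
    for p in populations:
        by_cond.setdefault(p.condition, []).append(p)
    for cond in [c for c, ps in by_cond.items() if len(ps) < 2]:
        warnings.warn(f"condition {cond!r} has < 2 populations; excluded from summary")
        del by_cond[cond]
    if len(by_cond) < 2:
        raise ValueError("need at least 2 conditions with >= 2 populations each")
    if control not in by_cond:
        raise ValueError(f"control condition {control!r} missing")

    def pop_value(p: PopulationSummary) -> float:
        return math.exp(p.mean_logratio) if scale == "geometric" else p.mean_ratio

    cond_values = {c: np.array([pop_value(p) for p in ps]) for c, ps in by_cond.items()}
    control_mean = float(np.mean(cond_values[control]))
    rows = []
    for cond in sorted(by_cond, key=lambda c: (c != control, c)):
        pct = 100.0 * cond_values[cond] / control_mean
        rows.append({
            "condition": cond, "n_populations": len(pct),
            "mean_pct_of_control": float(np.mean(pct)),
            "se_pct": float(np.std(pct, ddof=1) / np.sqrt(len(pct))),
        })
    table = pd.DataFrame(rows)

    # one-way ANOVA on log-scale per-population values
    logs = {c: np.log(v) for c, v in cond_values.items()}
    k = len(logs)
    n_total = sum(len(v) for v in logs.values())
    grand = np.mean(np.concatenate(list(logs.values())))
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in logs.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in logs.values())
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if ss_within == 0:
        f_stat, anova_p = 0.0, 1.0
    else:
        f_stat = float((ss_between / df_b) / mse)
        anova_p = float(f_dist.sf(f_stat, df_b, df_w))

    contrast_results = []
    for name, coefmap in (contrasts or {}).items():
        missing = [c for c in coefmap if c not in logs]
        if missing:
            raise ValueError(f"contrast {name!r} references unknown conditions {missing}")
        coefs = np.array([coefmap[c] for c in coefmap], dtype=float)
        if abs(coefs.sum()) > 1e-12:
            raise ValueError(f"contrast {name!r} coefficients must sum to 0")
        means = np.array([logs[c].mean() for c in coefmap])
        ns = np.array([len(logs[c]) for c in coefmap], dtype=float)
        est = float(coefs @ means)
        se = math.sqrt(mse * float(np.sum(coefs**2 / ns))) if mse > 0 else 0.0
        if se == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = est / se
            p = float(2 * t_dist.sf(abs(t_stat), df_w))
        contrast_results.append(
            {"contrast": name, "estimate_log": est, "t": t_stat, "df": df_w, "p": p}
        )
    return FlowConditionSummary(
        table=table, anova_f=f_stat, anova_p=anova_p, contrast_results=contrast_results
    )
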