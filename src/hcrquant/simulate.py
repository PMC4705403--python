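"""Synthetic-data generators emulating the statistical structure of the assay.

Four generators cover the pipeline's inputs so every downstream stage is testable
without external data:

* qPCR plates — Richards-sigmoid amplification curves with known initial quantity
  and per-cycle efficiency, plus additive Gaussian fluorescence noise;
* expression experiments — per-condition (RFP, GFP) expression pairs with GFP
  gamma-distributed (shape < 2, as observed for the transfection-control reporter)
  and RFP a condition-dependent fraction of GFP with multiplicative log-normal
  noise;
* flow-cytometry event tables — a two-component (induced / non-induced) model of
  log_e(RFP/GFP) pushed through a linear spectral-spillover matrix;
* amplicon read sets — the expected transcript with independent background
  substitutions (default rate 0.1%) plus at most one lesion-site event drawn from
  a class-probability profile.

Every generator takes its seed from its config and is bitwise deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import ConditionGroup, MeasurementPair
from .qpcr import AmplificationCurve, richards
from .variants import ReferenceTranscript

__all__ = [
    "CurveShape",
    "QpcrSimConfig",
    "ExperimentDesign",
    "FlowSimConfig",
    "ReadSimConfig",
    "simulate_qpcr_plate",
    "simulate_expression_experiment",
    "simulate_flow_events",
    "simulate_amplicon_reads",
]


@dataclass(frozen=True)
class CurveShape:
    """Noiseless curve shape: plateau Fmax, asymmetry d, optional slope scale b.

    The exponential phase of the Richards curve multiplies fluorescence by
    ``exp(d / b)`` per cycle, so b is determined by d and the configured true
    efficiency (b = d / ln Eff) and is normally left unset; supplying a b that
    contradicts the efficiency is rejected.
    """

    fmax: float = 1000.0
    #: Default asymmetry 0.25: baseline-subtracted real-time traces stay
    #: log-linear through the takeoff and bend over relatively few cycles,
    #: which in this family (with b tied to the efficiency) corresponds to
    #: d well below 1. The window-of-linearity efficiency estimator presumes
    #: exactly this regime.
    d: float = 0.25
    b: float | None = None

    def __post_init__(self):
        if self.fmax <= 0 or self.d <= 0 or (self.b is not None and self.b <= 0):
            raise ValueError("curve shape parameters must be positive")


@dataclass(frozen=True)
class QpcrSimConfig:
    """Configuration for one simulated qPCR plate.

    ``wells`` lists (well-id, amplicon, true initial quantity) triples; quantities
    are in the same arbitrary units as fluorescence (one unit of product produces
    one fluorescence unit).
    """

    wells: tuple
    true_efficiency: float = 2.0
    curve_shape: CurveShape = field(default_factory=CurveShape)
    #: Additive fluorescence noise, 0.2% of the default plateau — typical of
    #: baseline-subtracted traces from current real-time instruments.
    noise_sd: float = 2.0
    n_cycles: int = 45
    seed: int = 0

    def __post_init__(self):
        if not (1.0 < self.true_efficiency <= 2.0):
            raise ValueError(f"efficiency must lie in (1, 2], got {self.true_efficiency}")
        if self.n_cycles < 10:
            raise ValueError(f"need >= 10 cycles for a sigmoid, got {self.n_cycles}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        wells = tuple((str(w), str(a), float(q)) for w, a, q in self.wells)
        if not wells:
            raise ValueError("no wells configured")
        for w, _a, q in wells:
            if q <= 0:
                raise ValueError(f"well {w}: initial quantity must be positive, got {q}")
            if q >= self.curve_shape.fmax:
                raise ValueError(f"well {w}: initial quantity must be below Fmax")
        b_eff = self.curve_shape.d / math.log(self.true_efficiency)
        if self.curve_shape.b is not None and not math.isclose(
            self.curve_shape.b, b_eff, rel_tol=1e-6
        ):
            raise ValueError(
                f"curve_shape.b={self.curve_shape.b} contradicts efficiency "
                f"{self.true_efficiency} (requires b={b_eff:.4g})"
            )
        object.__setattr__(self, "wells", wells)

    @property
    def richards_b(self) -> float:
        return self.curve_shape.d / math.log(self.true_efficiency)


def simulate_qpcr_plate(config: QpcrSimConfig) -> tuple[list[AmplificationCurve], dict]:
    """Simulate one plate of amplification curves with known ground truth.

    The noiseless curve for a well with initial quantity Q is a Richards sigmoid
    placed so that its exponential phase equals ``Q * Eff**x``: the centre is
    ``c = ln(Fmax / Q) / ln(Eff)``. Two wells whose quantities differ by a factor
    f therefore have Cy0 values differing by exactly ``log_Eff(f)`` cycles.

    Returns the curves and a ground-truth record (per-well quantity, efficiency,
    and Richards parameters).
    """
    rng = np.random.default_rng(config.seed)
    eff = config.true_efficiency
    shape = config.curve_shape
    b = config.richards_b
    cycles = np.arange(1, config.n_cycles + 1)
    curves = []
    truth: dict = {"efficiency": eff, "wells": {}}
    for well_id, amplicon, quantity in config.wells:
        c = math.log(shape.fmax / quantity) / math.log(eff)
        clean = richards(cycles, shape.fmax, b, c, shape.d)
        noisy = clean + rng.normal(0.0, config.noise_sd, size=len(cycles)) \
            if config.noise_sd > 0 else clean
        curves.append(AmplificationCurve(
            well_id=well_id, amplicon=amplicon, cycles=cycles, fluorescence=noisy
        ))
        truth["wells"][well_id] = {
            "amplicon": amplicon, "initial_quantity": quantity, "efficiency": eff,
            "fmax": shape.fmax, "b": b, "c": c, "d": shape.d,
        }
    return curves, truth


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of an expression experiment over cell lines x vectors x time points.

    ``condition_effect`` maps (cell_line, vector, time_h) to the expected RFP/GFP
    fraction of control in [0, 1]; conditions not listed default to 1 (no
    suppression). GFP draws follow Gamma(shape, scale); the default shape 1.5 is
    below 2, reproducing the heavy-tailed 1/GFP regime the combination-ratio
    normalization is designed for. RFP noise is multiplicative log-normal with
    the given coefficient of variation and unit mean.
    """

    cell_lines: tuple[str, ...] = ("fibroblast",)
    vectors: tuple[str, ...] = ("control", "lesionA")
    time_points_h: tuple[float, ...] = (6.0, 18.0)
    n_replicates: int = 6
    gfp_gamma: tuple[float, float] = (1.5, 1.0)
    condition_effect: dict = field(default_factory=dict)
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not self.cell_lines or not self.vectors or not self.time_points_h:
            raise ValueError("design must name at least one cell line, vector and time point")
        if self.n_replicates < 3:
            raise ValueError(
                f"at least 3 replicate measurements per condition, got {self.n_replicates}"
            )
        k, theta = self.gfp_gamma
        if k <= 0 or theta <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(t < 0 for t in self.time_points_h):
            raise ValueError("time points must be non-negative")
        eff = {tuple(key): float(v) for key, v in self.condition_effect.items()}
        for key, v in eff.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"condition effect for {key} must lie in [0, 1], got {v}")
        object.__setattr__(self, "condition_effect", eff)

    def effect(self, cell_line: str, vector: str, time_h: float) -> float:
        return self.condition_effect.get((cell_line, vector, float(time_h)), 1.0)


def simulate_expression_experiment(
    design: ExperimentDesign,
) -> tuple[list[ConditionGroup], dict]:
    """Draw replicate (RFP, GFP) expression pairs for every condition.

    GFP ~ Gamma(k, theta); RFP = GFP x effect x exp(N(-sigma^2/2, sigma^2)) with
    sigma^2 = ln(1 + cv^2), so E[RFP | GFP] = GFP x effect exactly. Returns the
    condition groups plus the ground-truth effect surface.
    """
    rng = np.random.default_rng(design.seed)
    k, theta = design.gfp_gamma
    sigma = math.sqrt(math.log1p(design.noise_cv**2))
    groups = []
    truth: dict = {"effects": {}, "gfp_gamma": design.gfp_gamma, "noise_cv": design.noise_cv}
    for cell in design.cell_lines:
        for vector in design.vectors:
            for t in design.time_points_h:
                effect = design.effect(cell, vector, t)
                gfp = rng.gamma(k, theta, size=design.n_replicates)
                noise = (
                    np.exp(rng.normal(-sigma**2 / 2, sigma, size=design.n_replicates))
                    if sigma > 0 else np.ones(design.n_replicates)
                )
                rfp = gfp * effect * noise
                groups.append(ConditionGroup(
                    cell_line=cell, vector=vector, time_h=float(t),
                    pairs=[MeasurementPair(r, g) for r, g in zip(rfp, gfp)],
                ))
                truth["effects"][f"{cell}|{vector}|{t}"] = effect
    return groups, truth


@dataclass(frozen=True)
class FlowSimConfig:
    """Two-population flow simulation with linear spectral spillover.

    ``component_params`` gives (mean, sd) of log_e(RFP/GFP) for the non-induced
    and induced components; defaults place them 6 SD apart. ``spillover`` is a
    square matrix (rows = fluorophores RFP/GFP/APC, unit diagonal) applied to the
    true signals to produce the observed channels.
    """

    n_events: int = 10_000
    induced_fraction: float = 0.7
    component_params: dict = field(default_factory=lambda: {
        "non_induced": (-2.0, 0.5), "induced": (1.0, 0.5),
    })
    #: median true intensity of the GFP and APC channels; RFP's scale follows
    #: from GFP and the log-ratio components.
    channel_baselines: tuple[float, float] = (500.0, 50.0)
    spillover: np.ndarray = field(default_factory=lambda: np.eye(3))
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("need at least one event")
        if not (0.0 <= self.induced_fraction <= 1.0):
            raise ValueError("induced_fraction must lie in [0, 1]")
        for name in ("non_induced", "induced"):
            mu, sd = self.component_params[name]
            if sd <= 0:
                raise ValueError(f"{name} component sd must be positive")
        if any(b <= 0 for b in self.channel_baselines):
            raise ValueError("channel baselines must be positive")
        m = np.asarray(self.spillover, dtype=float)
        if m.shape != (3, 3) or not np.allclose(np.diag(m), 1.0) or np.any(m < 0):
            raise ValueError("spillover must be 3x3, non-negative, unit diagonal")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("spillover matrix is singular")
        object.__setattr__(self, "spillover", m)


def simulate_flow_events(config: FlowSimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a flow event table plus ground-truth induced labels.

    True GFP is log-normal around its baseline; true RFP = GFP * exp(r) with the
    log-ratio r drawn from the event's component; APC is uncorrelated
    autofluorescence. Observed channels are ``true @ spillover``. With an
    identity spillover the observed table equals the true signals, so per-event
    channel sums are conserved.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    induced = rng.random(n) < config.induced_fraction
    mu_n, sd_n = config.component_params["non_induced"]
    mu_i, sd_i = config.component_params["induced"]
    logratio = np.where(induced, rng.normal(mu_i, sd_i, n), rng.normal(mu_n, sd_n, n))
    b_gfp, b_apc = config.channel_baselines
    gfp = b_gfp * np.exp(rng.normal(0.0, 0.4, n))
    rfp = gfp * np.exp(logratio)
    apc = b_apc * np.exp(rng.normal(0.0, 0.3, n))
    true = np.column_stack([rfp, gfp, apc])
    observed = true @ config.spillover
    table = pd.DataFrame(observed, columns=["RFP", "GFP", "APC"])
    table.insert(0, "event", np.arange(n))
    return table, induced


@dataclass(frozen=True)
class ReadSimConfig:
    """Amplicon-read simulation around the lesion-opposite position.

    ``lesion_event_profile`` maps event keys (``misincorporation:A``,
    ``deletion``, ``insertion:G``) to probabilities summing to <= 1; the
    remainder is a correct (match) lesion base. Background substitutions are
    applied independently at every non-lesion position at
    ``background_error_rate`` (default 0.1%, the sequencing/RT background).
    """

    reference: ReferenceTranscript = None
    background_error_rate: float = 0.001
    lesion_event_profile: dict = field(default_factory=dict)
    n_reads: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.reference is None:
            from .variants import example_reference
            object.__setattr__(self, "reference", example_reference())
        if not (0.0 <= self.background_error_rate <= 1.0):
            raise ValueError("background error rate must lie in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("need at least one read")
        total = 0.0
        for key, p in self.lesion_event_profile.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"profile probability for {key!r} must lie in [0, 1]")
            kind = key.split(":")[0]
            if kind not in ("misincorporation", "insertion", "deletion"):
                raise ValueError(f"unknown lesion event class {key!r}")
            if kind in ("misincorporation", "insertion") and ":" not in key:
                raise ValueError(f"{key!r} needs a base, e.g. '{kind}:A'")
            total += p
        if total > 1.0 + 1e-12:
            raise ValueError(f"lesion event probabilities sum to {total} > 1")


_BASES = np.array(list("ACGU"))


def simulate_amplicon_reads(config: ReadSimConfig) -> list[tuple[str, str]]:
    """Simulate reads as (read-id, sequence) pairs in the RNA alphabet.

    Each read is the reference with (a) independent background substitutions at
    every non-lesion position and (b) at most one lesion-site event drawn from
    the profile: a substituted base, a deleted lesion base, or a base inserted
    immediately after the lesion-opposite position.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    seq = np.array(list(ref.sequence))
    lesion_idx = ref.lesion_opposite_pos - 1
    keys = list(config.lesion_event_profile)
    probs = np.array([config.lesion_event_profile[k] for k in keys], dtype=float)
    p_match = 1.0 - probs.sum()
    choices = keys + ["match"]
    all_probs = np.append(probs, p_match)

    reads = []
    for i in range(config.n_reads):
        bases = seq.copy()
        if config.background_error_rate > 0:
            hits = rng.random(len(bases)) < config.background_error_rate
            hits[lesion_idx] = False
            for j in np.nonzero(hits)[0]:
                alternatives = _BASES[_BASES != bases[j]]
                bases[j] = alternatives[rng.integers(0, 3)]
        event = choices[rng.choice(len(choices), p=all_probs)] if keys else "match"
        parts = list(bases)
        if event != "match":
            kind, _, base = event.partition(":")
            if kind == "misincorporation":
                parts[lesion_idx] = base
            elif kind == "deletion":
                del parts[lesion_idx]
            elif kind == "insertion":
                parts.insert(lesion_idx + 1, base)
        reads.append((f"read{i:05d}", "".join(parts)))
    return reads
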