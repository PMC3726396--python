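"""Voltage-clamp sensing-current and reporter-current quantification.

Off-sensing currents of a voltage sensor, recorded on stepping back to a
negative potential after a test pulse, are decomposed as an offset plus one
or two decaying exponentials,

    I(t) = I0 + Σ_i I_off,i · exp(−t / τ_off,i),        i = 1..N, N ∈ {1, 2}

with t = 0 at the off-pulse onset and the fit window starting at 5 ms to
exclude residual capacitive artefacts; amplitudes are reported extrapolated
back to t = 0. The translocated charge per component is the amplitude–time-
constant product Q_i = I_off,i · τ_off,i (µA·ms = nC), the total off-charge
is their sum, and the charge–voltage relation is fit with a Boltzmann
function

    Q(V) = A_min + (A_max − A_min) / (1 + exp(−z_q F (V − V_half) / (R T)))

yielding the midpoint potential V_half and effective valence z_q. Reporter-
channel traces (e.g. PI(4,5)P2-sensitive KCNQ2/3 currents co-expressed with
the phosphatase) are summarised by I_max, I_min, the inhibition ratio
1 − I_min/I_max, and the time τ50 to half-maximal inhibition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import constants

from .errors import AnalysisError, FitError, ParseError

__all__ = [
    "Protocol",
    "SweepTrace",
    "ExpFit",
    "ChargeDecomposition",
    "QVDataset",
    "BoltzmannFit",
    "ActivityMetrics",
    "fit_exp_decay",
    "choose_model",
    "decompose_charge",
    "build_qv",
    "fit_boltzmann",
    "boltzmann",
    "activity_metrics",
    "analyze_off_sweeps",
    "read_sweep_tsv",
    "write_sweep_tsv",
]

FARADAY = constants.value("Faraday constant")  # C/mol
GAS_CONSTANT = constants.R  # J/(mol K)
DEFAULT_TEMPERATURE_K = 295.15  # recordings at 21–23 °C
DEFAULT_FIT_START_MS = 5.0


@dataclass
class Protocol:
    """Voltage-step protocol metadata for a sweep."""

    holding_mV: float = -60.0
    test_mV: float = 80.0
    off_mV: float = -50.0
    test_duration_ms: float = 500.0
    off_duration_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.test_duration_ms <= 0 or self.off_duration_ms <= 0:
            raise AnalysisError("Protocol durations must be positive")


@dataclass
class SweepTrace:
    """A uniformly sampled current trace (ms, µA) with its protocol."""

    time: np.ndarray  # ms
    current: np.ndarray  # µA
    protocol: Protocol = field(default_factory=Protocol)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise AnalysisError("time and current must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise AnalysisError("A sweep needs at least two samples")
        deltas = np.diff(self.time)
        if np.any(deltas <= 0):
            raise AnalysisError("time must be strictly increasing")
        if not np.allclose(deltas, deltas[0], rtol=1e-6, atol=1e-9):
            raise AnalysisError("Sweep sampling must be uniform")
        if not np.all(np.isfinite(self.current)):
            raise AnalysisError("current contains non-finite samples")

    @property
    def sample_interval(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class ExpFit:
    """Parameters of an N-component exponential decay fit (canonical: τ ascending)."""

    n_components: int
    amplitudes: tuple[float, ...]  # µA, referenced to t = 0 of the off-pulse
    time_constants: tuple[float, ...]  # ms
    baseline: float  # µA
    chi2: float  # unweighted SSE over the fit window
    fit_start_ms: float = DEFAULT_FIT_START_MS
    window_span_ms: float = math.inf  # length of the fitted segment

    def __post_init__(self) -> None:
        if self.n_components not in (1, 2):
            raise FitError("n_components must be 1 or 2")
        if len(self.amplitudes) != self.n_components or len(self.time_constants) != self.n_components:
            raise FitError("Component count mismatch")
        if any(tau <= 0 for tau in self.time_constants):
            raise FitError("Time constants must be positive")
        if self.chi2 < 0:
            raise FitError("chi2 must be non-negative")
        order = np.argsort(self.time_constants)
        self.time_constants = tuple(self.time_constants[i] for i in order)
        self.amplitudes = tuple(self.amplitudes[i] for i in order)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.baseline)
        for a, tau in zip(self.amplitudes, self.time_constants):
            out = out + a * np.exp(-t / tau)
        return out


@dataclass
class ChargeDecomposition:
    """Off-charge split into fast and slow components (nC)."""

    Q_all: float
    Q_fast: float
    Q_slow: float

    def __post_init__(self) -> None:
        if not math.isclose(self.Q_all, self.Q_fast + self.Q_slow, rel_tol=0, abs_tol=1e-12 * max(1.0, abs(self.Q_all))):
            raise AnalysisError("Q_all must equal Q_fast + Q_slow")


@dataclass
class QVDataset:
    """Per-voltage off-charge table, optionally normalized at a reference voltage."""

    table: pd.DataFrame  # columns: test_mV, Q_all, Q_fast, Q_slow
    normalized: bool = False
    norm_voltage: Optional[float] = None


@dataclass
class BoltzmannFit:
    """Boltzmann Q–V parameters: midpoint, effective valence, asymptotes."""

    V_half: float  # mV
    z_q: float  # elementary charges
    A_min: float
    A_max: float
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.A_max <= self.A_min:
            raise FitError("A_max must exceed A_min")
        if self.z_q <= 0:
            raise FitError("z_q must be positive")

    def evaluate(self, v_mV: np.ndarray) -> np.ndarray:
        return boltzmann(np.asarray(v_mV, dtype=float), self.V_half, self.z_q, self.A_min, self.A_max, self.T)


@dataclass
class ActivityMetrics:
    """Reporter-channel inhibition summary."""

    I_max: float  # µA
    I_min: float  # µA
    inhibition_ratio: float  # 1 − I_min/I_max
    tau50_ms: Optional[float]  # time from I_max to half-maximal current; None if never reached

    def __post_init__(self) -> None:
        if self.I_min > self.I_max:
            raise AnalysisError("I_min cannot exceed I_max")


def boltzmann(
    v_mV: np.ndarray,
    v_half: float,
    z_q: float,
    a_min: float,
    a_max: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> np.ndarray:
    """Two-state Boltzmann charge–voltage curve (voltages in mV)."""
    arg = -z_q * FARADAY * (np.asarray(v_mV, dtype=float) - v_half) * 1e-3 / (
        GAS_CONSTANT * temperature_K
    )
    return a_min + (a_max - a_min) / (1.0 + np.exp(arg))


# ---------------------------------------------------------------------------
# Exponential decomposition
# ---------------------------------------------------------------------------

def _loglinear_tau(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(amplitude, tau) from a log-linear regression of |y| against t."""
    mask = np.abs(y) > 1e-12
    if np.count_nonzero(mask) < 2:
        return 0.0, max(float(t[-1] - t[0]) / 3.0, 1e-3)
    sign = 1.0 if np.median(y[mask]) >= 0 else -1.0
    slope, intercept = np.polyfit(t[mask], np.log(np.abs(y[mask])), 1)
    tau = -1.0 / slope if slope < -1e-12 else max(float(t[-1] - t[0]), 1e-3)
    return sign * float(np.exp(intercept)), float(tau)


def _initial_guesses(t: np.ndarray, y: np.ndarray, n: int) -> list[dict]:
    """Log-linear initialisation: tail → slow component, early residual → fast."""
    baseline0 = float(np.mean(y[-max(3, len(y) // 20):]))
    resid = y - baseline0
    tail_n = max(4, len(t) // 3)
    a_slow, tau_slow = _loglinear_tau(t[-tail_n:], resid[-tail_n:])
    if n == 1:
        a_all, tau_all = _loglinear_tau(t, resid)
        return [{"baseline": baseline0, "a1": a_all, "tau1": max(tau_all, 1e-3)}]
    early_n = max(4, len(t) // 4)
    early_resid = resid[:early_n] - a_slow * np.exp(-t[:early_n] / max(tau_slow, 1e-6))
    a_fast, tau_fast = _loglinear_tau(t[:early_n], early_resid)
    tau_fast = max(min(tau_fast, tau_slow / 2.0), 1e-3)
    if abs(a_fast) < 1e-12:
        a_fast = 0.5 * a_slow if abs(a_slow) > 0 else float(resid[0])
    return [
        {
            "baseline": baseline0,
            "a1": a_fast,
            "tau1": tau_fast,
            "a2": a_slow,
            "tau2": max(tau_slow, 2e-3),
        }
    ]


def _exp_model(n: int) -> lmfit.Model:
    if n == 1:
        def f(t, baseline, a1, tau1):
            return baseline + a1 * np.exp(-t / tau1)
    else:
        def f(t, baseline, a1, tau1, a2, tau2):
            return baseline + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    return lmfit.Model(f, independent_vars=["t"])


def fit_exp_decay(
    trace: SweepTrace,
    n_components: int,
    fit_start_ms: float = DEFAULT_FIT_START_MS,
    n_restarts: int = 5,
) -> ExpFit:
    """Least-squares exponential decomposition of an off-pulse segment.

    The trace must have t = 0 at the off-pulse onset; only samples with
    t ≥ ``fit_start_ms`` enter the unweighted least-squares fit, but the
    amplitudes refer to t = 0 (extrapolated through the fitted function).
    Initial values come from log-linear regressions of the tail and of the
    early residual; ``n_restarts`` seeded jittered restarts guard against
    local minima. χ² is the unweighted sum of squared residuals.
    """
    if n_components not in (1, 2):
        raise FitError(f"n_components must be 1 or 2, got {n_components}")
    mask = trace.time >= fit_start_ms - 1e-9
    t = trace.time[mask]
    y = trace.current[mask]
    if len(t) < 3 * n_components + 2:
        raise FitError("Fit window too short for the requested model")

    model = _exp_model(n_components)
    base_init = _initial_guesses(t, y, n_components)[0]
    rng = np.random.default_rng(20130729)  # fixed: restarts are deterministic
    inits = [base_init]
    for _ in range(n_restarts):
        jit = dict(base_init)
        for key in list(jit):
            if key.startswith("tau"):
                jit[key] = max(jit[key] * rng.lognormal(0.0, 0.6), 1e-3)
            elif key.startswith("a"):
                jit[key] = jit[key] * rng.lognormal(0.0, 0.3) if jit[key] != 0 else rng.normal(0, 0.1)
        inits.append(jit)

    span = float(t[-1] - t[0])
    best = None
    diagnostics = []
    for init in inits:
        params = model.make_params()
        for key, value in init.items():
            if key.startswith("tau"):
                params[key].set(value=value, min=1e-4, max=100.0 * span)
            else:
                params[key].set(value=value)
        try:
            result = model.fit(y, params, t=t)
        except Exception as exc:  # lmfit can raise on pathological starts
            diagnostics.append({"init": init, "error": str(exc)})
            continue
        if not np.all(np.isfinite(list(result.best_values.values()))):
            continue
        sse = float(np.sum(result.residual**2))
        if best is None or sse < best[0]:
            best = (sse, result)
    if best is None:
        raise FitError(
            "Exponential fit failed to converge from every start",
            diagnostics={"starts": diagnostics, "n_components": n_components},
        )
    sse, result = best
    values = result.best_values
    if n_components == 1:
        amps = (float(values["a1"]),)
        taus = (float(values["tau1"]),)
    else:
        amps = (float(values["a1"]), float(values["a2"]))
        taus = (float(values["tau1"]), float(values["tau2"]))
    return ExpFit(
        n_components=n_components,
        amplitudes=amps,
        time_constants=taus,
        baseline=float(values["baseline"]),
        chi2=sse,
        fit_start_ms=fit_start_ms,
        window_span_ms=span,
    )


def choose_model(
    fit1: ExpFit,
    fit2: ExpFit,
    noise_floor: float = 0.0,
    tau_ratio_min: float = 3.0,
) -> ExpFit:
    """Select mono- vs biexponential kinetics by χ², with a degeneracy guard.

    The biexponential is demoted to the monoexponential when its second
    component is not resolvable: time constants separated by less than
    ``tau_ratio_min``; either component's magnitude at the start of the fit
    window below ``noise_floor`` (µA) — a component that has already decayed
    by t = fit_start contributes nothing observable, however large its
    extrapolated t = 0 amplitude; or τ_slow exceeding the fitted window, where
    an exponential is indistinguishable from the baseline offset. Otherwise
    the fit with the smaller χ² wins.
    """
    if fit2.n_components == 2:
        tau_fast, tau_slow = fit2.time_constants
        if tau_slow / tau_fast < tau_ratio_min:
            return fit1
        observable = [
            abs(a) * math.exp(-fit2.fit_start_ms / tau)
            for a, tau in zip(fit2.amplitudes, fit2.time_constants)
        ]
        if min(observable) < noise_floor:
            return fit1
        if tau_slow > fit2.window_span_ms:
            return fit1
    return fit1 if fit1.chi2 <= fit2.chi2 else fit2


def decompose_charge(fit: ExpFit) -> ChargeDecomposition:
    """Charge per component Q_i = I_off,i · τ_off,i (µA · ms = nC).

    The baseline carries no charge. For a monoexponential fit the single
    component is the fast one and Q_slow = 0; Q_all = Q_fast + Q_slow holds
    exactly by construction.
    """
    charges = [a * tau for a, tau in zip(fit.amplitudes, fit.time_constants)]
    if fit.n_components == 1:
        q_fast, q_slow = charges[0], 0.0
    else:
        q_fast, q_slow = charges  # canonical ordering: ascending τ
    return ChargeDecomposition(Q_all=q_fast + q_slow, Q_fast=q_fast, Q_slow=q_slow)


def build_qv(
    decomps: dict[float, ChargeDecomposition],
    norm_voltage: float = 120.0,
) -> QVDataset:
    """Assemble per-voltage charges into a Q–V table normalized at ``norm_voltage``.

    Every Q column is divided by Q_all at the normalization voltage (default
    +120 mV), so the normalized Q_all there is exactly 1.
    """
    if norm_voltage not in decomps:
        raise AnalysisError(
            f"Normalization voltage {norm_voltage} mV missing from the dataset"
        )
    q_norm = decomps[norm_voltage].Q_all
    if q_norm == 0:
        raise AnalysisError("Q_all at the normalization voltage is zero")
    rows = [
        {
            "test_mV": v,
            "Q_all": d.Q_all / q_norm,
            "Q_fast": d.Q_fast / q_norm,
            "Q_slow": d.Q_slow / q_norm,
        }
        for v, d in sorted(decomps.items())
    ]
    return QVDataset(table=pd.DataFrame(rows), normalized=True, norm_voltage=norm_voltage)


def fit_boltzmann(
    qv: QVDataset,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> BoltzmannFit:
    """Fit the Q_all–V relation with a Boltzmann function (z_q constrained > 0)."""
    v = qv.table["test_mV"].to_numpy(dtype=float)
    q = qv.table["Q_all"].to_numpy(dtype=float)
    if len(v) < 5:
        raise FitError(f"Boltzmann fit needs ≥ 5 voltage points, got {len(v)}")

    model = lmfit.Model(
        lambda v_mV, v_half, z_q, a_min, a_max: boltzmann(
            v_mV, v_half, z_q, a_min, a_max, temperature_K
        ),
        independent_vars=["v_mV"],
    )
    q_min, q_max = float(np.min(q)), float(np.max(q))
    spread = max(q_max - q_min, 1e-9)
    mid = q_min + spread / 2.0
    v_half0 = float(v[np.argmin(np.abs(q - mid))])
    params = model.make_params(
        v_half=v_half0, z_q=1.0, a_min=q_min, a_max=q_max
    )
    params["z_q"].set(min=1e-3, max=20.0)
    result = model.fit(q, params, v_mV=v)
    if not result.success or not np.all(np.isfinite(list(result.best_values.values()))):
        raise FitError("Boltzmann fit did not converge", diagnostics={"report": result.fit_report()})
    bv = result.best_values
    return BoltzmannFit(
        V_half=float(bv["v_half"]),
        z_q=float(bv["z_q"]),
        A_min=float(bv["a_min"]),
        A_max=float(bv["a_max"]),
        T=temperature_K,
    )


def analyze_off_sweeps(
    sweeps: dict[float, SweepTrace],
    fit_start_ms: float = DEFAULT_FIT_START_MS,
    noise_floor: float = 1e-3,
    tau_ratio_min: float = 3.0,
    norm_voltage: float = 120.0,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> tuple[QVDataset, BoltzmannFit, dict[float, ExpFit]]:
    """Full off-current pipeline: fit, model-select, integrate, Boltzmann-fit.

    For every test voltage both a mono- and a biexponential decomposition are
    fit; the χ²/degeneracy criterion picks one; the chosen fit's charge
    decomposition enters the Q–V table, which is normalized at
    ``norm_voltage`` and fit with the Boltzmann function.
    """
    fits: dict[float, ExpFit] = {}
    decomps: dict[float, ChargeDecomposition] = {}
    for v, trace in sweeps.items():
        fit1 = fit_exp_decay(trace, 1, fit_start_ms)
        try:
            fit2 = fit_exp_decay(trace, 2, fit_start_ms)
        except FitError:
            fit2 = fit1
        chosen = choose_model(fit1, fit2, noise_floor, tau_ratio_min)
        fits[v] = chosen
        decomps[v] = decompose_charge(chosen)
    qv = build_qv(decomps, norm_voltage)
    bfit = fit_boltzmann(qv, temperature_K)
    return qv, bfit, fits


def activity_metrics(
    trace: SweepTrace,
    reference: str = "imax",
) -> ActivityMetrics:
    """Inhibition metrics of a reporter-channel sweep over the depolarization phase.

    I_max is the maximum current during the test phase; I_min the minimum
    after the time of I_max. The inhibition ratio is 1 − I_min/I_max and τ50
    is the first time the current falls to I_max/2, measured from the time of
    I_max (default) or from pulse onset with ``reference='onset'``; it is
    None when half-inhibition is never reached.
    """
    i = trace.current
    t = trace.time
    k_max = int(np.argmax(i))
    i_max = float(i[k_max])
    if i_max <= 0:
        raise AnalysisError("I_max ≤ 0: no measurable channel expression")
    i_min = float(np.min(i[k_max:]))
    ratio = 1.0 - i_min / i_max
    below = np.nonzero(i[k_max:] <= i_max / 2.0)[0]
    if len(below) == 0:
        tau50 = None
    else:
        t_cross = float(t[k_max + below[0]])
        tau50 = t_cross - (float(t[k_max]) if reference == "imax" else float(t[0]))
    return ActivityMetrics(
        I_max=i_max, I_min=i_min, inhibition_ratio=ratio, tau50_ms=tau50
    )


# ---------------------------------------------------------------------------
# Sweep TSV dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = {
    "holding_mV": "holding_mV",
    "test_mV": "test_mV",
    "off_mV": "off_mV",
    "test_duration_ms": "test_duration_ms",
    "off_duration_ms": "off_duration_ms",
}


def write_sweep_tsv(trace: SweepTrace) -> str:
    """Serialize a sweep: `# key=value` protocol header, then time/current rows."""
    p = trace.protocol
    lines = [
        f"# holding_mV={p.holding_mV:g}",
        f"# test_mV={p.test_mV:g}",
        f"# off_mV={p.off_mV:g}",
        f"# test_duration_ms={p.test_duration_ms:g}",
        f"# off_duration_ms={p.off_duration_ms:g}",
        f"# sample_interval_ms={trace.sample_interval:g}",
        "time_ms\tcurrent_uA",
    ]
    for t, c in zip(trace.time, trace.current):
        lines.append(f"{t:.6g}\t{c:.8g}")
    return "\n".join(lines) + "\n"


def read_sweep_tsv(text: str) -> SweepTrace:
    """Parse the sweep TSV dialect written by :func:`write_sweep_tsv`."""
    meta: dict[str, float] = {}
    times: list[float] = []
    currents: list[float] = []
    saw_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value)
                except ValueError as exc:
                    raise ParseError(f"Bad header value at line {lineno}") from exc
            continue
        if line.startswith("time_ms"):
            saw_header = True
            continue
        parts = line.split("\t")
        try:
            times.append(float(parts[0]))
            currents.append(float(parts[1]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"Malformed sweep row at line {lineno}") from exc
    if not saw_header or not times:
        raise ParseError("Sweep TSV lacks a time_ms/current_uA table")
    protocol = Protocol(
        holding_mV=meta.get("holding_mV", -60.0),
        test_mV=meta.get("test_mV", 80.0),
        off_mV=meta.get("off_mV", -50.0),
        test_duration_ms=meta.get("test_duration_ms", 500.0),
        off_duration_ms=meta.get("off_duration_ms", 500.0),
    )
    return SweepTrace(time=np.array(times), current=np.array(currents), protocol=protocol)
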