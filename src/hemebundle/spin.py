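"""Mössbauer doublet simulation/fitting and spin-state analysis.

Zero-field ⁵⁷Fe Mössbauer spectra of ferric hemes are modelled as sums of
Lorentzian quadrupole doublets over a constant baseline: each doublet
contributes two equal-depth lines at δ ± ΔE_Q/2 sharing one FWHM Γ.
:class:`MossbauerModel` fits that forward model to a measured spectrum by
seeded multistart nonlinear least squares and returns a
:class:`MossbauerResults` carrying the doublet parameters, their standard
errors, residual diagnostics and a ``summary()`` table.

The module also classifies (δ, ΔE_Q) pairs against literature ranges for
five- and six-coordinate high-spin Fe(III) hemes (with a quantum-admixed
QS candidate window), and implements the Maltempo estimate of the S=5/2
weight of an admixed S=3/2,5/2 state from perpendicular EPR g-values,
a₅/₂² = (g⊥ − 4)/2.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CoverageError, FitError, RangeError, ValidationError

__all__ = [
    "MossbauerDoublet",
    "MossbauerSpectrum",
    "EPRGSet",
    "SpinAdmixture",
    "SpinStateCall",
    "maltempo_fraction",
    "simulate_mossbauer",
    "MossbauerModel",
    "MossbauerResults",
    "fit_mossbauer",
    "classify_spin_state",
    "load_spin_ranges",
    "read_spectrum",
    "write_spectrum",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MossbauerDoublet:
    """One quadrupole doublet: isomer shift δ, splitting ΔE_Q, FWHM Γ
    (all mm/s) and its fraction of the total absorption area."""

    delta: float
    delta_EQ: float
    gamma: float
    area_fraction: float

    def __post_init__(self):
        if self.delta_EQ < 0:
            raise ValidationError("ΔE_Q must be >= 0")
        if self.gamma <= 0:
            raise ValidationError("Γ must be > 0")
        if not (0.0 <= self.area_fraction <= 1.0 + 1e-9):
            raise ValidationError("area fraction must be in [0, 1]")

    @property
    def line_positions(self) -> tuple[float, float]:
        return (self.delta - self.delta_EQ / 2.0, self.delta + self.delta_EQ / 2.0)


@dataclass
class MossbauerSpectrum:
    """Velocity grid (mm/s, strictly monotone) and baseline-normalized
    absorption signal; dips are negative-going relative to the baseline."""

    velocity: np.ndarray
    signal: np.ndarray
    noise_sd: float | None = None

    def __post_init__(self):
        v = np.asarray(self.velocity, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if v.ndim != 1 or v.shape != s.shape:
            raise ValidationError("velocity and signal must be equal-length 1-D")
        if not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
            raise ValidationError("velocity grid must be strictly monotone")
        self.velocity = v
        self.signal = s


@dataclass(frozen=True)
class EPRGSet:
    """Effective g-values of one ferric species plus rhombicity E/D."""

    g_x: float
    g_y: float
    g_z: float
    E_over_D: float = 0.0
    fraction: float = 1.0

    def __post_init__(self):
        if min(self.g_x, self.g_y, self.g_z) <= 0:
            raise ValidationError("g values must be > 0")
        if self.E_over_D < 0:
            raise ValidationError("E/D must be >= 0")

    @property
    def g_perp(self) -> float:
        return 0.5 * (self.g_x + self.g_y)


@dataclass(frozen=True)
class SpinAdmixture:
    """Weight of the S=5/2 component in a quantum-admixed spin state."""

    a52_squared: float
    g_perp_used: float
    clamped: bool = False


@dataclass(frozen=True)
class SpinStateCall:
    """All classification labels matched by a (δ, ΔE_Q) pair, plus the
    distance to each non-matching range."""

    labels: tuple[str, ...]
    distances: dict[str, float]


# ---------------------------------------------------------------------------
# Maltempo quantum-admixed spin analysis
# ---------------------------------------------------------------------------

def maltempo_fraction(
    g_set: EPRGSet | None = None, g_perp: float | None = None
) -> SpinAdmixture:
    """S=5/2 weight of an admixed state, a₅/₂² = (g⊥ − 4)/2.

    g⊥ is taken as the arithmetic mean of the two perpendicular g-values
    when a full g-set is given.  Pure limits: g⊥ = 4 is pure S=3/2,
    g⊥ = 6 pure S=5/2; values outside [3.5, 6.5] are rejected as
    physically implausible for this treatment, and mild excursions past
    the pure limits are clamped with a flag.
    """
    if (g_set is None) == (g_perp is None):
        raise ValidationError("give exactly one of g_set or g_perp")
    gp = g_set.g_perp if g_set is not None else float(g_perp)
    if gp < 3.5 or gp > 6.5:
        raise RangeError(
            f"g_perp = {gp:.3f} outside the plausible [3.5, 6.5] window"
        )
    raw = (gp - 4.0) / 2.0
    clamped = not (0.0 <= raw <= 1.0)
    return SpinAdmixture(
        a52_squared=float(np.clip(raw, 0.0, 1.0)),
        g_perp_used=gp,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# Forward model and simulation
# ---------------------------------------------------------------------------

def _lorentz(v: np.ndarray, v0: float, gamma: float) -> np.ndarray:
    # unit-peak Lorentzian with FWHM gamma
    h = 0.5 * gamma
    return h * h / ((v - v0) ** 2 + h * h)


def _doublet_signal(
    v: np.ndarray, delta: float, d_eq: float, gamma: float, amp: float
) -> np.ndarray:
    lo, hi = delta - d_eq / 2.0, delta + d_eq / 2.0
    return amp * (_lorentz(v, lo, gamma) + _lorentz(v, hi, gamma))


def _amplitudes_from_fractions(
    doublets: Sequence[MossbauerDoublet], total_depth: float
) -> np.ndarray:
    # line amplitude amp_k ∝ f_k / Γ_k keeps integrated areas in the
    # requested fractions (line area = amp·π·Γ/2 per line); scaled so the
    # amplitudes sum to total_depth — a lone doublet has line depth
    # total_depth, and a collapsed doublet (ΔE_Q = 0) dips 2×total_depth.
    f = np.array([d.area_fraction for d in doublets])
    g = np.array([d.gamma for d in doublets])
    w = f / g
    return total_depth * w / w.sum()


def simulate_mossbauer(
    doublets: Sequence[MossbauerDoublet],
    grid: np.ndarray,
    total_depth: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    baseline: float = 0.0,
) -> MossbauerSpectrum:
    """Simulate a zero-field spectrum as a sum of Lorentzian doublets.

    ``total_depth`` sets the summed line amplitude; ``noise_sd`` adds
    i.i.d. Gaussian noise with the given seed.  The grid must cover
    every line position ± 3Γ.
    """
    if not doublets:
        raise ValidationError("need at least one doublet")
    fsum = sum(d.area_fraction for d in doublets)
    if abs(fsum - 1.0) > 1e-9:
        raise ValidationError(f"area fractions sum to {fsum}, not 1")
    v = np.asarray(grid, dtype=float)
    lo = min(min(d.line_positions) - 3 * d.gamma for d in doublets)
    hi = max(max(d.line_positions) + 3 * d.gamma for d in doublets)
    if v.min() > lo or v.max() < hi:
        raise CoverageError(
            f"grid [{v.min():.2f}, {v.max():.2f}] does not cover lines ± 3Γ "
            f"[{lo:.2f}, {hi:.2f}]"
        )
    amps = _amplitudes_from_fractions(doublets, total_depth)
    signal = np.full_like(v, baseline, dtype=float)
    for d, a in zip(doublets, amps):
        signal -= _doublet_signal(v, d.delta, d.delta_EQ, d.gamma, a)
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        signal = signal + rng.normal(0.0, noise_sd, size=v.shape)
    return MossbauerSpectrum(velocity=v, signal=signal,
                             noise_sd=noise_sd if noise_sd > 0 else None)


# ---------------------------------------------------------------------------
# Fitting: Model / Results
# ---------------------------------------------------------------------------

class MossbauerResults:
    """Fit results: doublet parameters, uncertainties and diagnostics.

    Attributes
    ----------
    doublets : list[MossbauerDoublet]
        Canonical order (ascending ΔE_Q); area fractions normalized.
    baseline : float
    params : ndarray
        Flat parameter vector ``[baseline, (δ, ΔE_Q, Γ, amp) × k]``.
    bse : ndarray
        Asymptotic standard errors (NaN where the Jacobian is rank-
        deficient).
    """

    def __init__(self, model, params, cost, residuals, jac, n_starts_used,
                 warnings_):
        self.model = model
        self.params = params
        self.cost = float(cost)
        self.residuals = residuals
        self.nobs = residuals.size
        self.df_resid = self.nobs - params.size
        self.rss = float(residuals @ residuals)
        self.rmse = float(np.sqrt(self.rss / self.nobs))
        self.n_starts_used = n_starts_used
        self.warnings = list(warnings_)

        # asymptotic covariance from the Jacobian at the optimum
        self.bse = np.full(params.size, np.nan)
        try:
            jtj = jac.T @ jac
            s2 = self.rss / max(self.df_resid, 1)
            cov = s2 * np.linalg.pinv(jtj)
            self.bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass

        self.baseline = float(params[0])
        k = model.n_doublets
        raw = params[1:].reshape(k, 4)
        order = np.argsort(raw[:, 1])          # canonical: ascending ΔE_Q
        raw = raw[order]
        self._param_order = order
        areas = raw[:, 3] * raw[:, 2]          # amp · Γ ∝ integrated area
        fractions = areas / areas.sum()
        self.doublets = [
            MossbauerDoublet(
                delta=float(d), delta_EQ=float(q), gamma=float(g),
                area_fraction=float(f),
            )
            for (d, q, g, _), f in zip(raw, fractions)
        ]
        self.area_fractions = fractions

    def predict(self, velocity: np.ndarray | None = None) -> np.ndarray:
        v = self.model.spectrum.velocity if velocity is None else np.asarray(velocity)
        return self.model._forward(self.params, v)

    def summary(self) -> str:
        lines = [
            "Mössbauer quadrupole-doublet fit",
            "=" * 64,
            f"n_points: {self.nobs}   n_doublets: {self.model.n_doublets}   "
            f"starts used: {self.n_starts_used}",
            f"baseline: {self.baseline:+.5f}   RMSE: {self.rmse:.5f}   "
            f"RSS: {self.rss:.6g}",
            "-" * 64,
            f"{'doublet':>7s} {'δ (mm/s)':>10s} {'ΔE_Q (mm/s)':>12s} "
            f"{'Γ (mm/s)':>10s} {'area %':>8s}",
        ]
        for i, d in enumerate(self.doublets, 1):
            lines.append(
                f"{i:>7d} {d.delta:>10.3f} {d.delta_EQ:>12.3f} "
                f"{d.gamma:>10.3f} {100 * d.area_fraction:>8.1f}"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "doublet": i + 1,
                    "delta": d.delta,
                    "delta_EQ": d.delta_EQ,
                    "gamma": d.gamma,
                    "area_percent": 100 * d.area_fraction,
                }
                for i, d in enumerate(self.doublets)
            ]
        )


class MossbauerModel:
    """Lorentzian quadrupole-doublet model of a zero-field spectrum.

    Parameters
    ----------
    spectrum : MossbauerSpectrum
    n_doublets : int in {1, 2, 3}

    ``fit()`` runs bounded nonlinear least squares; without explicit
    initial values it uses a seeded multistart (default 20 starts, the
    first data-driven) and keeps the best optimum.
    """

    def __init__(self, spectrum: MossbauerSpectrum, n_doublets: int = 2):
        if n_doublets not in (1, 2, 3):
            raise ValidationError("n_doublets must be 1, 2 or 3")
        n_free = 1 + 4 * n_doublets
        if spectrum.velocity.size < 10 * n_free:
            raise ValidationError(
                f"need >= {10 * n_free} points for {n_free} free parameters, "
                f"got {spectrum.velocity.size}"
            )
        self.spectrum = spectrum
        self.n_doublets = n_doublets

    # -- forward model -----------------------------------------------------
    def _forward(self, params: np.ndarray, v: np.ndarray) -> np.ndarray:
        out = np.full_like(v, params[0], dtype=float)
        for k in range(self.n_doublets):
            d, q, g, a = params[1 + 4 * k : 5 + 4 * k]
            out -= _doublet_signal(v, d, q, g, a)
        return out

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        return self._forward(params, self.spectrum.velocity) - self.spectrum.signal

    # -- starting values ---------------------------------------------------
    def _data_driven_start(self) -> np.ndarray:
        v, s = self.spectrum.velocity, self.spectrum.signal
        base = float(np.percentile(s, 90))
        depth = max(base - float(s.min()), 1e-6)
        absorb = np.clip(base - s, 0, None)
        w = absorb / absorb.sum() if absorb.sum() > 0 else np.ones_like(s) / s.size
        center = float((w * v).sum())
        spread = float(np.sqrt((w * (v - center) ** 2).sum()))
        params = [base]
        for k in range(self.n_doublets):
            q = 2.0 * spread * (k + 1) / self.n_doublets
            params += [center, q, 0.3, depth / self.n_doublets]
        return np.array(params)

    def _random_start(self, rng: np.random.Generator) -> np.ndarray:
        v, s = self.spectrum.velocity, self.spectrum.signal
        base = float(np.percentile(s, 90))
        depth = max(base - float(s.min()), 1e-6)
        span = float(v.max() - v.min())
        params = [base]
        for _ in range(self.n_doublets):
            params += [
                rng.uniform(v.min() + 0.25 * span, v.max() - 0.25 * span),
                rng.uniform(0.0, 0.8 * span),
                rng.uniform(0.15, 0.6),
                depth * rng.uniform(0.2, 1.0),
            ]
        return np.array(params)

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.spectrum.velocity
        span = float(v.max() - v.min())
        lo, hi = [-np.inf], [np.inf]
        for _ in range(self.n_doublets):
            lo += [v.min(), 0.0, 0.01, 0.0]
            hi += [v.max(), 1.5 * span, 2.0, np.inf]
        return np.array(lo), np.array(hi)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        init: Sequence[MossbauerDoublet] | np.ndarray | None = None,
        n_starts: int = 20,
        seed: int = 0,
        max_nfev: int = 2000,
    ) -> MossbauerResults:
        """Fit the doublet model; returns :class:`MossbauerResults`.

        ``init`` may be a list of :class:`MossbauerDoublet` (a single
        local fit is run from there) or a raw parameter vector; when
        absent, ``n_starts`` seeded starts (one data-driven, the rest
        random) are tried and the best kept.
        """
        lo, hi = self._bounds()
        starts: list[np.ndarray] = []
        if init is not None:
            if isinstance(init, np.ndarray):
                starts = [init.astype(float)]
            else:
                base = float(np.percentile(self.spectrum.signal, 90))
                amps = _amplitudes_from_fractions(list(init),
                    max(base - float(self.spectrum.signal.min()), 1e-6))
                p = [base]
                for d, a in zip(init, amps):
                    p += [d.delta, d.delta_EQ, d.gamma, a / 2.0]
                starts = [np.array(p)]
        else:
            rng = np.random.default_rng(seed)
            starts = [self._data_driven_start()]
            starts += [self._random_start(rng) for _ in range(n_starts - 1)]

        best = None
        n_used = 0
        for p0 in starts:
            p0 = np.clip(p0, lo, hi + (np.where(np.isinf(hi), 0, -1e-12)))
            try:
                res = least_squares(
                    self._residuals, p0, bounds=(lo, hi), max_nfev=max_nfev
                )
            except Exception:
                continue
            n_used += 1
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError(
                "no start converged for the Mössbauer fit",
                best_cost=None,
            )

        warnings_ = []
        # boundary / identifiability diagnostics
        tol = 1e-6 * (1.0 + np.abs(best.x))
        at_bound = (np.abs(best.x - lo) < tol) | (np.abs(best.x - hi) < tol)
        if np.any(at_bound[1:]):
            warnings_.append("parameter(s) at a bound; estimates unreliable")
        dq = sorted(best.x[2::4][: self.n_doublets])
        gm = best.x[3::4][: self.n_doublets]
        if self.n_doublets >= 2 and (dq[1] - dq[0]) < float(np.max(gm)):
            warnings_.append(
                "ΔE_Q separation below linewidth; doublets weakly identifiable"
            )
        return MossbauerResults(
            self, best.x, best.cost, best.fun, best.jac, n_used, warnings_
        )


def fit_mossbauer(
    spectrum: MossbauerSpectrum,
    n_doublets: int = 2,
    init: Sequence[MossbauerDoublet] | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> MossbauerResults:
    """Functional wrapper over :class:`MossbauerModel` + ``fit()``."""
    return MossbauerModel(spectrum, n_doublets).fit(
        init=init, n_starts=n_starts, seed=seed
    )


# ---------------------------------------------------------------------------
# Spin-state classification
# ---------------------------------------------------------------------------

def load_spin_ranges(path: str | Path | None = None) -> dict[str, dict]:
    """Classification ranges; default table ships with the package."""
    if path is None:
        ref = importlib.resources.files("hemebundle.data") / "spin_ranges.json"
        obj = json.loads(ref.read_text())
    else:
        obj = json.loads(Path(path).read_text())
    return obj["ranges"]


def _range_distance(x: float, lohi: list[float]) -> float:
    lo, hi = lohi
    if x < lo:
        return lo - x
    if x > hi:
        return x - hi
    return 0.0


def classify_spin_state(
    delta: float, delta_EQ: float, ranges: dict[str, dict] | None = None
) -> SpinStateCall:
    """Classify a (δ, ΔE_Q) pair against ferric-heme literature ranges.

    Every matching label is returned — overlapping ranges never get
    silently disambiguated — together with each range's distance
    (Euclidean over the per-axis shortfalls, 0 inside).  No match yields
    the explicit ``unclassified`` call.
    """
    if ranges is None:
        ranges = load_spin_ranges()
    labels = []
    distances = {}
    for name, spec in ranges.items():
        dd = _range_distance(delta, spec["delta"])
        dq = _range_distance(delta_EQ, spec["delta_EQ"])
        dist = float(np.hypot(dd, dq))
        distances[name] = dist
        if dist == 0.0:
            labels.append(name)
    if not labels:
        labels = ["unclassified"]
    return SpinStateCall(labels=tuple(labels), distances=distances)


# ---------------------------------------------------------------------------
# Spectrum I/O
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path) -> MossbauerSpectrum:
    """Two-column text: velocity (mm/s) and signal."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns")
    return MossbauerSpectrum(velocity=data[:, 0], signal=data[:, 1])


def write_spectrum(spectrum: MossbauerSpectrum, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.velocity, spectrum.signal]),
        header="velocity_mm_s signal",
        fmt="%.6f",
    )
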