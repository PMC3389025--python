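"""Drawing values for uncertain parameters.

Two routes, matching the two distribution constructs:

* a symbolic p.d.f. is turned into a numeric CDF by quadrature after the
  change of variable ``w = tan(u)`` (which maps the whole real line onto
  ``(-pi/2, pi/2)`` so the improper integral gets finite limits), and then
  inverted at a uniform deviate by bracketing plus damped least-squares
  refinement of ``(F(y) - z)^2``;
* a realisation vector is sampled by picking an index uniformly, returning
  joint tuples whole.

All randomness flows through :class:`RngStream`, a seeded Mersenne-Twister
stream, so runs are reproducible from a single seed.
"""

from __future__ import annotations

import math
from bisect import bisect_right, insort
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, optimize

from .errors import (DensityNormalizationError, EvaluationError,
                     IntegrationError, InversionError, NumericError)
from .mathml import Environment, compile_lambda
from .model import DensitySpec, RealisationsSpec

_HALF_PI = math.pi / 2.0
_Z_CLAMP = 1e-12


@dataclass
class QuadratureSettings:
    rule: str = "adaptive"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_subdivisions: int = 200
    normalization_tolerance: float = 1e-3
    inversion_tol: float = 1e-8  # on the CDF scale


class RngStream:
    """Seeded Mersenne-Twister uniform stream.

    Identical seeds yield identical streams; ``next_uniform`` returns values
    strictly inside (0, 1).
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.generator = np.random.RandomState(self.seed)

    def next_uniform(self) -> float:
        u = float(self.generator.random_sample())
        while u <= 0.0:  # random_sample may return exactly 0.0
            u = float(self.generator.random_sample())
        return u

    def next_normal(self, mean: float = 0.0, sd: float = 1.0) -> float:
        return float(self.generator.normal(mean, sd))

    def spawn(self, offset: int) -> "RngStream":
        return RngStream(self.seed + offset)


class NumericCdf:
    """A cached, monotone CDF numerically integrated from a symbolic p.d.f.

    Construction integrates the transformed density over the full line,
    failing if the total mass is not 1 within ``normalization_tolerance``,
    and spot-checks monotonicity on the seeding grid.  Evaluations always
    integrate from the nearest fixed checkpoint and are memoized, so F(y)
    is a pure function of y: results are bit-for-bit independent of query
    order, and repeated inversions stay cheap.
    """

    _SEED_GRID = 65  # checkpoints used for normalization + monotone check

    def __init__(self, spec: DensitySpec, env: Optional[Environment] = None,
                 settings: Optional[QuadratureSettings] = None):
        self.spec = spec
        self.settings = settings or QuadratureSettings()
        bindings = dict(env.bindings) if env is not None else {}
        pdf = compile_lambda(spec.pdf, bindings)

        def transformed(u: float) -> float:
            w = math.tan(u)
            cos_u = math.cos(u)
            try:
                fw = pdf(w)
            except EvaluationError:
                raise
            except (OverflowError, ValueError) as exc:
                raise EvaluationError(f"p.d.f. evaluation failed: {exc}")
            return fw / (cos_u * cos_u)

        self._pdf = pdf
        self._g = transformed
        # fixed (u, unnormalized F(tan u)) checkpoints + per-point memo
        self._us = [-_HALF_PI]
        self._Fs = [0.0]
        self._memo = {}
        self._seed_cache()

    # -- construction helpers ------------------------------------------------

    def _quad(self, a: float, b: float) -> float:
        if b <= a:
            return 0.0
        s = self.settings
        out = integrate.quad(self._g, a, b, epsabs=s.abs_tol,
                             epsrel=s.rel_tol, limit=s.max_subdivisions,
                             full_output=1)
        value, abserr = out[0], out[1]
        if len(out) > 3:  # QUADPACK warning message present
            limit = max(s.abs_tol, s.rel_tol * max(abs(value), 1.0)) * 1e4
            if abserr > limit:
                raise IntegrationError(
                    f"quadrature did not converge on [{a:g}, {b:g}] "
                    f"(estimate {value:g}, error {abserr:g})", estimate=value)
        return value

    def _seed_cache(self):
        grid = np.linspace(-_HALF_PI, _HALF_PI, self._SEED_GRID)
        total = 0.0
        tol = self.settings.normalization_tolerance
        for a, b in zip(grid[:-1], grid[1:]):
            inc = self._quad(float(a), float(b))
            if inc < -10.0 * self.settings.abs_tol - 1e-12:
                raise DensityNormalizationError(
                    "p.d.f. is negative on part of its domain "
                    f"(mass {inc:g} on a subinterval)", normalization=None)
            total += max(inc, 0.0)
            self._us.append(float(b))
            self._Fs.append(total)
        self.normalization = total
        if abs(total - 1.0) > tol:
            raise DensityNormalizationError(
                f"p.d.f. integrates to {total:.6g}, not 1 "
                f"(tolerance {tol:g}); not a valid density",
                normalization=total)

    # -- evaluation ----------------------------------------------------------

    def _raw_cdf_u(self, u: float) -> float:
        """Unnormalized F at transformed coordinate u (pure in u)."""
        hit = self._memo.get(u)
        if hit is not None:
            return hit
        i = bisect_right(self._us, u)
        # nearest fixed checkpoint at or below u
        j = i - 1
        base_u, base_F = self._us[j], self._Fs[j]
        if base_u == u:
            return base_F
        value = base_F + max(self._quad(base_u, u), 0.0)
        value = min(value, self.normalization)
        self._memo[u] = value
        return value

    def cdf_value(self, y: float) -> float:
        """F(y) in [0, 1] (mass below y divided by total mass)."""
        if math.isnan(y):
            raise EvaluationError("cdf_value at NaN")
        if y == math.inf:
            return 1.0
        if y == -math.inf:
            return 0.0
        u = math.atan(y)
        return min(self._raw_cdf_u(u) / self.normalization, 1.0)

    # -- inversion -----------------------------------------------------------

    def _bracket(self, z: float):
        """Finite y-interval [lo, hi] with F(lo) <= z <= F(hi)."""
        target = z * self.normalization
        i = bisect_right(self._Fs, target)
        j = max(i - 1, 0)
        u_lo = self._us[j]
        u_hi = self._us[min(i, len(self._us) - 1)]
        lo = math.tan(max(u_lo, -_HALF_PI + 1e-12))
        hi = math.tan(min(u_hi, _HALF_PI - 1e-12))
        # expand outward if quadrature noise put z outside [F(lo), F(hi)]
        step = 1.0
        for _ in range(200):
            if self.cdf_value(lo) <= z:
                break
            lo -= step
            step *= 2.0
        else:
            raise InversionError(f"could not bracket z={z:g} from below",
                                 best=lo)
        step = 1.0
        for _ in range(200):
            if self.cdf_value(hi) >= z:
                break
            hi += step
            step *= 2.0
        else:
            raise InversionError(f"could not bracket z={z:g} from above",
                                 best=hi)
        return lo, hi

    def _left_edge(self, y: float, z: float) -> float:
        """Smallest y' with F(y') within tolerance of z (plateau rule)."""
        ftol = self.settings.inversion_tol
        delta = max(1e-9, abs(y) * 1e-9)
        edge = y
        for _ in range(80):
            probe = edge - delta
            if self.cdf_value(probe) >= z - ftol:
                edge = probe
                delta *= 2.0
            else:
                break
        else:
            return edge
        if edge == y:
            return y
        # bisect between the last failing probe and the plateau edge
        lo, hi = edge - delta / 2.0, edge
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if self.cdf_value(mid) >= z - ftol:
                hi = mid
            else:
                lo = mid
            if hi - lo < max(1e-12, abs(hi) * 1e-12):
                break
        return hi

    def invert(self, z: float) -> float:
        """Smallest y with |F(y) - z| within the inversion tolerance."""
        if not (0.0 < z < 1.0):
            raise InversionError(f"z={z!r} outside (0, 1)")
        z = min(max(z, _Z_CLAMP), 1.0 - _Z_CLAMP)
        ftol = self.settings.inversion_tol
        lo, hi = self._bracket(z)

        root = None
        if hi > lo:
            # damped least-squares refinement of (F(y) - z)^2
            x0 = 0.5 * (lo + hi)
            try:
                res = optimize.least_squares(
                    lambda y: self.cdf_value(float(y[0])) - z, [x0],
                    method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=200)
                cand = float(res.x[0])
                if lo - 1e-9 <= cand <= hi + 1e-9 and \
                        abs(self.cdf_value(cand) - z) <= ftol:
                    root = cand
            except NumericError:
                root = None
            if root is None:
                # bracketing restart: guaranteed-convergent root find
                try:
                    root = float(optimize.brentq(
                        lambda y: self.cdf_value(y) - z, lo, hi,
                        xtol=1e-13, rtol=1e-14, maxiter=300))
                except ValueError as exc:
                    raise InversionError(
                        f"inversion failed at z={z:g}: {exc}", best=x0)
        else:
            root = lo

        if abs(self.cdf_value(root) - z) > 10.0 * ftol:
            raise InversionError(
                f"inversion stalled at y={root:g} "
                f"(|F(y)-z|={abs(self.cdf_value(root) - z):g})", best=root)
        return self._left_edge(root, z)

    def sample(self, rng: RngStream) -> float:
        """One inverse-transform draw; consumes exactly one uniform deviate."""
        return self.invert(rng.next_uniform())


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def cdf_value(cdf: NumericCdf, y: float) -> float:
    return cdf.cdf_value(y)


def invert_cdf(cdf: NumericCdf, z: float) -> float:
    return cdf.invert(z)


def sample_density(spec: DensitySpec, env: Optional[Environment],
                   rng: RngStream,
                   settings: Optional[QuadratureSettings] = None,
                   cdf: Optional[NumericCdf] = None) -> float:
    """Inverse-transform draw from a symbolic density.

    Pass a prebuilt ``cdf`` to amortize CDF construction over many draws.
    """
    if cdf is None:
        cdf = NumericCdf(spec, env, settings)
    return cdf.sample(rng)


def sample_realisations(spec: RealisationsSpec, rng: RngStream):
    """Uniform index pick; joint tuples are returned whole, never mixed."""
    n = len(spec.realisations)
    z = rng.next_uniform()
    index = min(int(z * n), n - 1)
    return spec.realisations[index]


@dataclass
class ParameterDraw:
    values: dict = field(default_factory=dict)  # (component, variable) -> real
    provenance: list = field(default_factory=list)


class ParameterSampler:
    """Samples a full parameter set for a model's assertions.

    Numeric CDFs are constructed once, so ensembles pay the quadrature
    set-up cost a single time per density.
    """

    def __init__(self, assertions, env: Optional[Environment] = None,
                 settings: Optional[QuadratureSettings] = None):
        seen = set()
        for a in assertions:
            for t in a.targets:
                if t.key in seen:
                    raise NumericError(
                        f"assertions are not target-disjoint: {t.variable!r}")
                seen.add(t.key)
        self.assertions = list(assertions)
        self.env = env or Environment()
        self.settings = settings or QuadratureSettings()
        self._cdfs = {}
        for i, a in enumerate(self.assertions):
            if isinstance(a.spec, DensitySpec):
                try:
                    self._cdfs[i] = NumericCdf(a.spec, self.env, self.settings)
                except NumericError as exc:
                    names = ", ".join(t.variable for t in a.targets)
                    raise type(exc)(f"[{names}] {exc}") from exc

    def draw(self, rng: RngStream) -> ParameterDraw:
        out = ParameterDraw()
        for i, a in enumerate(self.assertions):
            names = ", ".join(t.variable for t in a.targets)
            try:
                if isinstance(a.spec, DensitySpec):
                    z = rng.next_uniform()
                    x = self._cdfs[i].invert(z)
                    out.values[a.targets[0].key] = x
                    out.provenance.append(
                        {"targets": names, "kind": "density", "uniform": z})
                else:
                    n = len(a.spec.realisations)
                    z = rng.next_uniform()
                    index = min(int(z * n), n - 1)
                    picked = a.spec.realisations[index]
                    values = picked if isinstance(picked, tuple) else (picked,)
                    for t, v in zip(a.targets, values):
                        out.values[t.key] = v
                    out.provenance.append(
                        {"targets": names, "kind": "realisations",
                         "index": index})
            except NumericError as exc:
                raise type(exc)(f"[{names}] {exc}") from exc
        return out


def draw_parameter_set(assertions, env: Optional[Environment],
                       rng: RngStream,
                       settings: Optional[QuadratureSettings] = None,
                       sampler: Optional[ParameterSampler] = None
                       ) -> ParameterDraw:
    """One Monte-Carlo draw over all assertions, in document order."""
    if sampler is None:
        sampler = ParameterSampler(assertions, env, settings)
    return sampler.draw(rng)
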