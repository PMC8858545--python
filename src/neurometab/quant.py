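"""Toy linear-combination spectral quantifier with Cramér–Rao %SD.

A deliberately simple, synthetic stand-in for a full clinical MRS
quantifier: spectra are synthesized as linear combinations of per-metabolite
basis lineshapes (sums of Lorentzian or Gaussian peaks on a ppm axis) plus
a low-order polynomial baseline and white noise, and concentrations are
re-estimated by non-negative linear least squares.  Because the model is
linear in the concentrations, the Cramér–Rao lower bound on each estimate
is the corresponding diagonal element of sigma^2 (G^T G)^-1 with G the
design matrix restricted to the active (non-zero) parameters, and is
reported as %SD = 100 * sqrt(var) / estimate — the same quality metric
downstream CRLB filtering consumes.

This module makes no claim of parity with clinical quantifiers; its role
is to generate mechanistically meaningful CRLB values for the pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize

__all__ = [
    "Peak",
    "BasisSet",
    "Spectrum",
    "QuantResult",
    "CollinearBasisError",
    "synthesize_spectrum",
    "fit_linear_combination",
    "default_basis",
]


class CollinearBasisError(ValueError):
    """Raised when basis lineshapes are (numerically) linearly dependent."""

    def __init__(self, metabolites):
        self.metabolites = tuple(metabolites)
        super().__init__(f"collinear basis vectors: {', '.join(self.metabolites)}")


@dataclass(frozen=True)
class Peak:
    center_ppm: float
    amplitude: float
    linewidth_ppm: float

    def __post_init__(self):
        if self.linewidth_ppm <= 0:
            raise ValueError("linewidth must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class BasisSet:
    """Per-metabolite peak tables with a common lineshape kind."""

    peaks: dict[str, tuple[Peak, ...]]
    lineshape: str = "lorentzian"

    def __post_init__(self):
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        for name, pk in self.peaks.items():
            if len(pk) == 0:
                raise ValueError(f"metabolite {name!r} has no peaks")

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(self.peaks)

    def profile(self, name: str, ppm: np.ndarray) -> np.ndarray:
        """Unit-concentration lineshape of one metabolite on a ppm grid."""
        out = np.zeros_like(ppm, dtype=float)
        for pk in self.peaks[name]:
            hw = pk.linewidth_ppm / 2.0
            if self.lineshape == "lorentzian":
                out += pk.amplitude * hw**2 / ((ppm - pk.center_ppm) ** 2 + hw**2)
            else:
                sig = pk.linewidth_ppm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                out += pk.amplitude * np.exp(-0.5 * ((ppm - pk.center_ppm) / sig) ** 2)
        return out

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# lineshape: {self.lineshape}\n")
        buf.write("# metabolite\tcenter_ppm\tamplitude\tlinewidth_ppm\n")
        for name, pks in self.peaks.items():
            for pk in pks:
                buf.write(f"{name}\t{pk.center_ppm:g}\t{pk.amplitude:g}\t{pk.linewidth_ppm:g}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "BasisSet":
        lineshape = "lorentzian"
        peaks: dict[str, list[Peak]] = {}
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("# lineshape:"):
                lineshape = line.split(":", 1)[1].strip()
            if not line or line.startswith("#"):
                continue
            name, c, a, w = line.split("\t")
            peaks.setdefault(name, []).append(Peak(float(c), float(a), float(w)))
        return cls({k: tuple(v) for k, v in peaks.items()}, lineshape)


@dataclass
class Spectrum:
    """A 1H spectrum on a strictly monotone-decreasing ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    noise_sd: float | None = None

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-d arrays of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass
class QuantResult:
    """Concentration estimates with CRLB %SD and estimate covariance."""

    concentrations: dict[str, float]
    crlb_pct: dict[str, float]
    covariance: np.ndarray
    metabolites: tuple[str, ...]
    noise_sd: float
    baseline_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    residual: np.ndarray | None = field(default=None, repr=False)


def default_ppm_axis(n: int = 2048, lo: float = 0.2, hi: float = 10.0) -> np.ndarray:
    """Conventional decreasing ppm grid covering the 1H metabolite region."""
    return np.linspace(hi, lo, n)


def default_basis() -> BasisSet:
    """A small synthetic basis with well-separated singlet-like resonances.

    Peak positions follow the familiar 1H landmarks (NAA 2.01, Cr/PCr
    3.03/3.93, cholines ~3.2, Glu/Gln 2.1-2.4, myo-Ins 3.56, Lac 1.31 ppm);
    amplitudes and linewidths are stylized, not literature lineshapes.
    """
    p = {
        "NAA": [Peak(2.01, 1.0, 0.04)],
        "Cr": [Peak(3.03, 0.6, 0.04), Peak(3.93, 0.4, 0.04)],
        "PCr": [Peak(3.05, 0.55, 0.04), Peak(3.95, 0.35, 0.04)],
        "Glu": [Peak(2.35, 0.45, 0.06), Peak(3.75, 0.25, 0.05)],
        "Gln": [Peak(2.45, 0.4, 0.06), Peak(3.77, 0.2, 0.05)],
        "GABA": [Peak(1.89, 0.3, 0.06), Peak(2.28, 0.25, 0.06), Peak(3.01, 0.2, 0.06)],
        "Ins": [Peak(3.56, 0.7, 0.04), Peak(4.06, 0.2, 0.05)],
        "Tau": [Peak(3.26, 0.4, 0.05), Peak(3.42, 0.4, 0.05)],
        "Lac": [Peak(1.31, 0.8, 0.04)],
        "Ala": [Peak(1.47, 0.5, 0.04)],
    }
    return BasisSet({k: tuple(v) for k, v in p.items()}, "lorentzian")


def synthesize_spectrum(
    basis: BasisSet,
    concentrations: dict[str, float],
    baseline_coeffs=(0.0,),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    ppm: np.ndarray | None = None,
) -> Spectrum:
    """Linear-combination spectrum: sum_m c_m basis_m(ppm) + baseline + noise.

    The baseline is a polynomial in ppm with the given coefficients
    (constant first); noise is iid Normal(0, noise_sd), deterministic for a
    fixed seed.
    """
    unknown = set(concentrations) - set(basis.metabolites)
    if unknown:
        raise ValueError(f"concentrations name metabolites absent from basis: {sorted(unknown)}")
    if any(c < 0 for c in concentrations.values()):
        raise ValueError("concentrations must be non-negative")
    if ppm is None:
        ppm = default_ppm_axis()
    y = np.zeros_like(ppm)
    for name, c in concentrations.items():
        y += c * basis.profile(name, ppm)
    y += npoly.polyval(ppm, np.asarray(baseline_coeffs, dtype=float))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=ppm.shape)
    return Spectrum(ppm=ppm, intensity=y, noise_sd=noise_sd if noise_sd > 0 else None)


def _design(basis: BasisSet, ppm: np.ndarray, baseline_degree: int) -> tuple[np.ndarray, list[str]]:
    cols = [basis.profile(name, ppm) for name in basis.metabolites]
    names = list(basis.metabolites)
    # scale ppm to [-1, 1] for a well-conditioned polynomial block
    t = 2 * (ppm - ppm.min()) / (ppm.max() - ppm.min()) - 1
    for d in range(baseline_degree + 1):
        cols.append(t**d)
        names.append(f"baseline^{d}")
    return np.column_stack(cols), names


def _check_collinear(G: np.ndarray, names: list[str], n_met: int) -> None:
    Gm = G[:, :n_met]
    norms = np.linalg.norm(Gm, axis=0)
    zero = norms == 0
    if zero.any():
        raise CollinearBasisError([names[i] for i in np.flatnonzero(zero)])
    C = (Gm / norms).T @ (Gm / norms)
    close = np.argwhere(np.triu(np.abs(C), 1) > 1 - 1e-10)
    if len(close):
        bad = sorted({names[i] for pair in close for i in pair})
        raise CollinearBasisError(bad)
    if np.linalg.matrix_rank(G) < G.shape[1]:
        raise CollinearBasisError(names[:n_met])


def fit_linear_combination(
    spec: Spectrum,
    basis: BasisSet,
    baseline_degree: int = 2,
    noise_sd: float | None = None,
    noise_window_ppm: tuple[float, float] = (9.0, 10.0),
) -> QuantResult:
    """Non-negative linear least squares fit of a spectrum to a basis set.

    Concentrations are constrained to be >= 0 (they are physical); baseline
    polynomial coefficients are unconstrained.  The estimate covariance is
    sigma^2 (G_A^T G_A)^-1 on the active set (parameters not pinned at the
    zero bound), and crlb_pct = 100 * sqrt(var) / estimate; a zero estimate
    reports an infinite %SD.  When ``noise_sd`` is not given it is
    estimated from the fit residual inside a signal-free ppm window
    (default 9-10 ppm).
    """
    mets = list(basis.metabolites)
    G, names = _design(basis, spec.ppm, baseline_degree)
    n_par = G.shape[1]
    if len(spec.ppm) <= n_par:
        raise ValueError("spectrum grid shorter than number of free parameters")
    _check_collinear(G, names, len(mets))

    lb = np.concatenate([np.zeros(len(mets)), np.full(baseline_degree + 1, -np.inf)])
    ub = np.full(n_par, np.inf)
    sol = optimize.lsq_linear(G, spec.intensity, bounds=(lb, ub), tol=1e-12)
    beta = sol.x
    resid = spec.intensity - G @ beta

    if noise_sd is None:
        noise_sd = spec.noise_sd
    if noise_sd is None:
        lo, hi = sorted(noise_window_ppm)
        mask = (spec.ppm >= lo) & (spec.ppm <= hi)
        if mask.sum() < 8:
            raise ValueError("noise window contains too few points to estimate noise")
        noise_sd = float(resid[mask].std(ddof=1))

    # active set: metabolites off the zero bound, plus all baseline terms
    active = np.concatenate([beta[: len(mets)] > 1e-12, np.ones(baseline_degree + 1, bool)])
    GA = G[:, active]
    cov_active = noise_sd**2 * np.linalg.inv(GA.T @ GA)
    cov = np.full((n_par, n_par), np.nan)
    ia = np.flatnonzero(active)
    cov[np.ix_(ia, ia)] = cov_active

    conc = {m: float(beta[i]) for i, m in enumerate(mets)}
    crlb = {}
    for i, m in enumerate(mets):
        if conc[m] <= 1e-12:
            crlb[m] = float("inf")
        else:
            crlb[m] = float(100.0 * np.sqrt(cov[i, i]) / conc[m])
    return QuantResult(
        concentrations=conc,
        crlb_pct=crlb,
        covariance=cov[: len(mets), : len(mets)],
        metabolites=tuple(mets),
        noise_sd=float(noise_sd),
        baseline_coeffs=beta[len(mets):],
        residual=resid,
    )
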