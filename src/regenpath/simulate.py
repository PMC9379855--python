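"""Synthetic data with the statistical structure the analysis assumes.

Three generators mirror the three analysis stages:

* :func:`gen_marker_tables` draws zero-one metAFLP marker matrices with
  prescribed per-context SV/DMV/DNMV event rates,
* :func:`gen_spectra` builds leaf-like ATR-FTIR spectra as sums of Gaussian
  bands (including the S-H thiol band near 2,545 cm^-1) plus slow baseline
  drift and white noise,
* :func:`gen_sem_data` simulates multivariate observations from a recursive
  path model (variables generated in topological order as linear combinations
  of their parents plus Gaussian residuals).

All generators are deterministic given the seed.  Default settings emulate the
triticale anther-culture study: event rates at the published CHH/CHG/CG means,
per-trial thiol-band levels spanning the observed 0.004-0.006 integrated
absorbance, and path coefficients/variances taken from the model fitted to the
packaged observation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import sem
from .ftir import NORMALIZATION_WINDOW, Spectrum, TrialSpectra
from .metaflp import Context, MarkerTable

__all__ = [
    "MarkerConfig",
    "SpectraConfig",
    "SemConfig",
    "GeneratorConfig",
    "gen_marker_tables",
    "gen_spectra",
    "gen_sem_data",
    "study_sem_config",
    "TRIAL_SIZES",
]

#: Regenerants per experimental trial in the study design.
TRIAL_SIZES = {"A": 3, "B": 5, "C": 3, "D": 10, "E": 5, "F": 3, "G": 4, "H": 4}


# ---------------------------------------------------------------------------
# Marker matrices


@dataclass
class MarkerConfig:
    """Per-context event rates and table shape.

    ``rates`` maps context -> (sv, dmv, dnmv); defaults are the published
    per-context means (CHH DMV was not reported and defaults to 0).
    ``meth_share`` is the fraction of donor loci that are methylated
    (band on KPN only); every donor locus carries a KPN band, since loci
    enter the analysis by being scored in the donor.
    """

    n_sites: dict[str, int] = field(default_factory=lambda: {"CG": 10_000, "CHG": 10_000, "CHH": 10_000})
    rates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "CHH": (0.0865, 0.0, 0.0058),
            "CHG": (0.2364, 0.0290, 0.0182),
            "CG": (0.1166, 0.0142, 0.0111),
        }
    )
    inconsistency_rate: float = 0.01
    meth_share: float = 0.30
    n_regenerants: int = 1

    def validate(self) -> None:
        for ctx, (sv, dmv, dnmv) in self.rates.items():
            Context(ctx)
            if min(sv, dmv, dnmv) < 0:
                raise ValueError(f"negative rate in context {ctx}")
            if sv + dmv + dnmv + self.inconsistency_rate > 1:
                raise ValueError(f"rates in context {ctx} sum above 1")
            if dmv > self.meth_share or dnmv > 1 - self.meth_share:
                raise ValueError(
                    f"context {ctx}: DMV rate must not exceed meth_share and "
                    f"DNMV rate must not exceed 1 - meth_share"
                )
        if not 0 < self.meth_share < 1:
            raise ValueError("meth_share must lie in (0, 1)")


_EXTENSIONS = {"CHH": ("AA", "AT", "TA", "TT"), "CG": ("TCG", "ACG"), "CHG": ("CAG", "CCG", "CTG")}


def gen_marker_tables(cfg: MarkerConfig, rng: np.random.Generator) -> MarkerTable:
    """Draw a donor + regenerant marker table with prescribed event rates.

    Donor loci are unmethylated (Acc65I + KpnI bands) or methylated (KpnI band
    only); each regenerant independently undergoes SV / DMV / DNMV /
    inconsistency events at the configured unconditional rates, so the
    quantification stage recovers them within binomial error.
    """
    cfg.validate()
    regs = [f"R{i + 1}" for i in range(cfg.n_regenerants)]
    frames = []
    for ctx, n in cfg.n_sites.items():
        sv, dmv, dnmv = cfg.rates[Context(ctx).value]
        inc = cfg.inconsistency_rate
        meth = rng.random(n) < cfg.meth_share  # donor methylation state per locus
        ext = rng.choice(_EXTENSIONS[Context(ctx).value], size=n)
        acc_d = (~meth).astype(int)
        kpn_d = np.ones(n, dtype=int)
        cols_acc = {"D": acc_d}
        cols_kpn = {"D": kpn_d}
        for r in regs:
            u = rng.random(n)
            # events conditioned on donor state so unconditional rates are exact
            p_meth_evt = np.where(meth, dmv / cfg.meth_share, dnmv / (1 - cfg.meth_share))
            is_sv = u < sv
            is_inc = (u >= sv) & (u < sv + inc)
            is_me = (u >= sv + inc) & (u < sv + inc + p_meth_evt)
            # regenerant bands per code family (see metaflp truth table)
            acc_r = np.where(meth, np.where(is_me, 1, 0), np.where(is_sv | is_me, 0, 1))
            kpn_r = np.where(is_sv, 0, 1)
            # inconsistency: regenerant Acc65I band without KpnI band
            # (code 1110 for unmethylated donors, 0110 for methylated ones)
            acc_r = np.where(is_inc, 1, acc_r)
            kpn_r = np.where(is_inc, 0, kpn_r)
            cols_acc[r] = acc_r.astype(int)
            cols_kpn[r] = kpn_r.astype(int)
        ids = [f"{ctx}_{i:05d}" for i in range(n)]
        for plat, cols in (("ACC", cols_acc), ("KPN", cols_kpn)):
            frames.append(
                pd.DataFrame({"locus_id": ids, "platform": plat, "primer_extension": ext, **cols})
            )
    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(["locus_id", "platform"], kind="stable").reset_index(drop=True)
    return MarkerTable(data, donor="D")


# ---------------------------------------------------------------------------
# FTIR spectra


#: Leaf-matrix band library (center cm^-1, Gaussian sigma cm^-1, amplitude):
#: broad O-H/N-H around 3,324, C-H stretch, Amide I/II, the 1,399 cm^-1
#: complex band, and the carbohydrate fingerprint with its 1,048 maximum.
_LEAF_BANDS: tuple[tuple[float, float, float], ...] = (
    (3324.0, 120.0, 0.60),
    (2925.0, 30.0, 0.25),
    (1645.0, 40.0, 0.80),
    (1538.0, 35.0, 0.30),
    (1399.0, 30.0, 0.40),
    (1150.0, 40.0, 0.30),
    (1048.0, 50.0, 1.00),
)

# Per-trial mean of the study's normalized 2,540-2,550 cm^-1 integrals.
_TRIAL_GSH = {
    "A": 0.004952, "B": 0.004896, "C": 0.004642, "D": 0.005353,
    "E": 0.004889, "F": 0.005244, "G": 0.005497, "H": 0.005323,
}


@dataclass
class SpectraConfig:
    """Band library and noise model for synthetic leaf spectra.

    ``gsh_level`` is the target unit-area-normalized integral of the S-H band
    over 2,540-2,550 cm^-1 per trial; the band amplitude is calibrated
    analytically so the noiseless spectrum reproduces it.
    """

    grid: tuple[float, float, float] = (600.0, 3700.0, 1.0)
    bands: tuple[tuple[float, float, float], ...] = _LEAF_BANDS
    sh_center: float = 2545.0
    sh_sigma: float = 4.0
    gsh_level: dict[str, float] = field(default_factory=lambda: dict(_TRIAL_GSH))
    n_spectra: dict[str, int] = field(default_factory=lambda: dict(TRIAL_SIZES))
    noise_sd: float = 5e-4
    drift_amplitude: float = 0.01
    amplitude_jitter: float = 0.03

    def validate(self) -> None:
        if self.sh_sigma <= 0 or any(s <= 0 for _, s, _ in self.bands):
            raise ValueError("band widths must be positive")
        if self.grid[2] <= 0 or self.grid[0] >= self.grid[1]:
            raise ValueError("invalid wavenumber grid")


def _gauss(w: np.ndarray, c: float, s: float, a: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((w - c) / s) ** 2)


def _gauss_integral(c: float, s: float, a: float, lo: float, hi: float) -> float:
    z = 1.0 / (s * math.sqrt(2.0))
    return a * s * math.sqrt(math.pi / 2.0) * (math.erf((hi - c) * z) - math.erf((lo - c) * z))


def gen_spectra(cfg: SpectraConfig, rng: np.random.Generator) -> dict[str, TrialSpectra]:
    """Generate one :class:`TrialSpectra` per trial.

    Each spectrum is the leaf band sum plus a calibrated S-H band, a slow
    sinusoidal drift and Gaussian noise; band amplitudes are jittered
    multiplicatively between regenerants of a trial.
    """
    cfg.validate()
    lo, hi, step = cfg.grid
    w = np.arange(lo, hi + step / 2, step)
    leaf = np.zeros_like(w)
    for c, s, a in cfg.bands:
        leaf += _gauss(w, c, s, a)
    # unit-area calibration: normalized S-H window integral == gsh_level
    fp_area = sum(_gauss_integral(c, s, a, *NORMALIZATION_WINDOW) for c, s, a in cfg.bands)
    unit_sh = _gauss_integral(cfg.sh_center, cfg.sh_sigma, 1.0, 2540.0, 2550.0)
    out = {}
    for trial, n in cfg.n_spectra.items():
        level = cfg.gsh_level[trial]
        spectra = []
        for _ in range(n):
            jitter = 1.0 + cfg.amplitude_jitter * rng.standard_normal()
            sh_amp = level * fp_area / unit_sh * max(jitter, 0.1)
            a = leaf * (1.0 + cfg.amplitude_jitter * rng.standard_normal())
            a = a + _gauss(w, cfg.sh_center, cfg.sh_sigma, sh_amp)
            if cfg.drift_amplitude:
                phase = rng.uniform(0, 2 * np.pi)
                a = a + cfg.drift_amplitude * np.sin(2 * np.pi * (w - w[0]) / (w[-1] - w[0]) + phase)
            if cfg.noise_sd:
                a = a + rng.normal(0.0, cfg.noise_sd, size=w.size)
            spectra.append(Spectrum(w.copy(), a, provenance=[f"synthetic:{trial}"]))
        out[trial] = TrialSpectra(trial=trial, spectra=spectra)
    return out


# ---------------------------------------------------------------------------
# Path-model observations


@dataclass
class SemConfig:
    """Path coefficients, variances and sampling design for model simulation."""

    variables: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]
    coefficients: dict[tuple[str, str], float]
    residual_variances: dict[str, float]  # one per endogenous variable
    exogenous: dict[str, dict]  # name -> {"levels": [...], "probs": [...]} or {"mean":, "var":}
    means: dict[str, float] = field(default_factory=dict)
    n: int = 37

    def model(self) -> sem.PathModel:
        return sem.build_model(self.variables, self.paths)

    def validate(self) -> None:
        m = self.model()  # raises on cycles/duplicates
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if set(self.coefficients) != set(self.paths):
            raise ValueError("coefficients must cover exactly the declared paths")
        if set(self.residual_variances) != set(m.endogenous):
            raise ValueError("residual_variances must cover exactly the endogenous variables")
        if any(v <= 0 for v in self.residual_variances.values()):
            raise ValueError("residual variances must be positive")
        if set(self.exogenous) != set(m.exogenous):
            raise ValueError("exogenous spec must cover exactly the exogenous variables")


def study_sem_config(n: int = 37) -> SemConfig:
    """Generator settings matching the study: the model of the anther-culture
    analysis with coefficients and variances fitted to the packaged table, and
    Cu(II) drawn from the design levels with the empirical multiplicities."""
    from .dataset import STUDY_VARIABLES, load_study_table
    from .pipeline import study_model

    records = load_study_table()
    model = study_model()
    moments = sem.sample_moments(records, STUDY_VARIABLES)
    fit = sem.fit_ml(model, moments)
    coefs = {
        (s, t): float(fit.estimates[f"{s} -> {t}"]) for s, t in model.paths
    }
    resid = {v: float(fit.estimates[f"resid({v})"]) for v in model.endogenous}
    cu = records["cu"].to_numpy()
    levels, counts = np.unique(cu, return_counts=True)
    return SemConfig(
        variables=tuple(model.variables),
        paths=tuple(model.paths),
        coefficients=coefs,
        residual_variances=resid,
        exogenous={"cu": {"levels": levels.tolist(), "probs": (counts / counts.sum()).tolist()}},
        means={v: float(moments.means[v]) for v in model.variables},
        n=n,
    )


def gen_sem_data(cfg: SemConfig, rng: np.random.Generator, residuals: str = "gaussian") -> pd.DataFrame:
    """Simulate observations from the path model.

    Exogenous variables are drawn from their configured discrete levels (or a
    normal law); endogenous variables follow in topological order as linear
    combinations of their parents plus independent residuals.  ``residuals``
    is ``"gaussian"`` (reference case) or ``"uniform"`` (matched variance,
    robustness stress).
    """
    cfg.validate()
    model = cfg.model()
    n = cfg.n
    data: dict[str, np.ndarray] = {}
    for v in cfg.exogenous:
        spec = cfg.exogenous[v]
        if "levels" in spec:
            data[v] = rng.choice(np.asarray(spec["levels"], float), size=n, p=spec.get("probs"))
        else:
            data[v] = rng.normal(spec["mean"], math.sqrt(spec["var"]), size=n)
    import graphlib

    deps = {v: set(model.parents(v)) for v in model.variables}
    for v in graphlib.TopologicalSorter(deps).static_order():
        if v in data:
            continue
        psi = cfg.residual_variances[v]
        if residuals == "gaussian":
            eps = rng.normal(0.0, math.sqrt(psi), size=n)
        elif residuals == "uniform":
            half = math.sqrt(3.0 * psi)
            eps = rng.uniform(-half, half, size=n)
        else:
            raise ValueError(f"unknown residual law {residuals!r}")
        mu_v = cfg.means.get(v, 0.0)
        y = np.full(n, mu_v, dtype=float) + eps
        for s in model.parents(v):
            y = y + cfg.coefficients[(s, v)] * (data[s] - cfg.means.get(s, 0.0))
        data[v] = y
    return pd.DataFrame({v: data[v] for v in model.variables})


@dataclass
class GeneratorConfig:
    """Bundle of the three stage generators plus the master seed."""

    seed: int = 0
    marker: MarkerConfig = field(default_factory=MarkerConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    sem: SemConfig | None = None  # None -> study_sem_config() on first use

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
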