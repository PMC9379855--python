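"""ATR-FTIR spectral preprocessing and thiol-band quantification.

The analysis pipeline treats a mid-infrared absorbance spectrum of leaf tissue
as a proxy assay for reduced glutathione (GSH): the S-H stretching vibration
absorbs near 2,530-2,550 cm^-1 where little else does, so after baseline
correction and unit-area normalization over the 900-1,800 cm^-1 fingerprint
region, the integrated absorbance over 2,540-2,550 cm^-1 serves as the GSH
feature.  Spectra are additionally summarized into successive 10 cm^-1 bins
over 600-1,780 and 2,450-3,700 cm^-1 (the 1,800-2,450 cm^-1 region is skipped
because of atmospheric CO2 / water-vapour interference), and within-trial
variability is profiled as the pointwise SD/mean ratio.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "Spectrum",
    "BinnedSpectrum",
    "TrialSpectra",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "baseline_correct",
    "normalize_unit_area",
    "bin_10cm",
    "band_area",
    "gsh_band",
    "sd_mean_ratio",
    "BIN_WINDOWS",
    "GSH_WINDOW",
    "NORMALIZATION_WINDOW",
]

#: 10 cm^-1 binning windows; the gap between them is the CO2/water-vapour region.
BIN_WINDOWS: tuple[tuple[float, float], ...] = ((600.0, 1780.0), (2450.0, 3700.0))
#: Integration window of the S-H stretch feature (cm^-1).
GSH_WINDOW: tuple[float, float] = (2540.0, 2550.0)
#: Fingerprint window whose trapezoid area is scaled to 1.
NORMALIZATION_WINDOW: tuple[float, float] = (900.0, 1800.0)


class SpectrumParseError(ValueError):
    pass


@dataclass
class Spectrum:
    """Wavenumber grid (cm^-1, strictly increasing) + absorbance, with provenance."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or w.shape != a.shape:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        if w.size >= 2 and w[0] > w[-1]:  # instruments often write descending grids
            w, a = w[::-1], a[::-1]
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise ValueError("non-finite values in spectrum")
        self.wavenumbers, self.absorbance = w, a

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, a: np.ndarray, step: str) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), a, self.provenance + [step])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavenumbers, self.absorbance)


@dataclass
class BinnedSpectrum:
    """Per-bin summaries over the two analysis windows.

    ``bin_edges[i]`` are the edges of window *i*'s contiguous 10 cm^-1 tiling;
    bins are half-open [lo, hi) with the final bin closed.  ``missing`` marks
    bins the spectrum's grid does not fully cover.
    """

    bin_edges: tuple[np.ndarray, ...]
    bin_values: tuple[np.ndarray, ...]
    missing: tuple[np.ndarray, ...]
    stat: str

    @property
    def n_bins(self) -> int:
        return sum(v.size for v in self.bin_values)


@dataclass
class TrialSpectra:
    """All regenerant spectra belonging to one experimental trial (A-H)."""

    trial: str
    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError(f"trial {self.trial!r} has no spectra")


# ---------------------------------------------------------------------------
# I/O

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"


def _read_jcamp(lines: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: AFFN ##XYPOINTS=(XY..XY) and ##XYDATA=(X++(Y..Y))."""
    xf = yf = 1.0
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    deltax = None
    for raw in lines:
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = re.sub(r"[\s_-]", "", key).upper()
            val = val.strip()
            if key == "XFACTOR":
                xf = float(val)
            elif key == "YFACTOR":
                yf = float(val)
            elif key == "DELTAX":
                deltax = float(val)
            elif key == "XYPOINTS":
                mode = "xy"
            elif key == "XYDATA":
                mode = "xpp"
            elif key == "END":
                break
            continue
        nums = [float(t) for t in re.findall(_NUM, line)]
        if mode == "xy":
            if len(nums) % 2:
                raise SpectrumParseError(f"odd XY pair count in line {line!r}")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
        elif mode == "xpp":
            if not nums:
                continue
            x0, yvals = nums[0], nums[1:]
            if deltax is None:
                raise SpectrumParseError("XYDATA without DELTAX is not supported")
            xs.extend(x0 + i * deltax for i in range(len(yvals)))
            ys.extend(yvals)
    if len(xs) < 2:
        raise SpectrumParseError("no data table found in JCAMP-DX input")
    return np.asarray(xs) * xf, np.asarray(ys) * yf


def read_spectrum(path, dialect: str = "auto") -> Spectrum:
    """Read a spectrum from two-column delimited text or (minimal) JCAMP-DX.

    ``dialect`` is ``"auto"``, ``"delimited"`` or ``"jcamp"``.  Descending
    grids are flipped to ascending on ingest.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "auto":
        dialect = "jcamp" if any(l.lstrip().startswith("##TITLE") for l in lines[:5]) else "delimited"
    if dialect == "jcamp":
        w, a = _read_jcamp(lines)
    elif dialect == "delimited":
        w_list, a_list = [], []
        for i, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,;\t ]+", line)
            if len(parts) < 2:
                raise SpectrumParseError(f"line {i}: expected two columns, got {line!r}")
            try:
                w_list.append(float(parts[0]))
                a_list.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"line {i}: non-numeric value in {line!r}") from exc
        w, a = np.asarray(w_list), np.asarray(a_list)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if w.size < 2:
        raise SpectrumParseError("spectrum needs at least 2 points")
    order = np.argsort(w) if not (np.all(np.diff(w) > 0) or np.all(np.diff(w) < 0)) else slice(None)
    w, a = w[order], a[order]
    if np.any(np.diff(np.sort(w)) == 0):
        raise SpectrumParseError("duplicate wavenumbers in input")
    return Spectrum(w, a, provenance=[f"read:{dialect}"])


def write_spectrum(s: Spectrum, path, sep: str = "\t") -> None:
    np.savetxt(path, np.column_stack([s.wavenumbers, s.absorbance]), delimiter=sep, fmt="%.10g")


# ---------------------------------------------------------------------------
# Preprocessing


def _rubberband(w: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Lower convex hull baseline (Andrew's monotone chain on the lower side)."""
    pts = list(zip(w, a))
    hull: list[tuple[float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) <= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    hx, hy = zip(*hull)
    return np.interp(w, hx, hy)


def _asls(a: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    n = a.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    w = np.ones(n)
    z = a
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + lam * D.T @ D).tocsc(), w * a)
        w = np.where(a > z, p, 1.0 - p)
    return z


def baseline_correct(
    s: Spectrum,
    method: str = "rubberband",
    *,
    lam: float = 1e7,
    p: float = 0.01,
    n_iter: int = 10,
) -> Spectrum:
    """Subtract an estimated baseline.

    Methods: ``linear-endpoints`` (line through the first and last point),
    ``rubberband`` (lower convex hull), ``asls`` (asymmetric least squares
    with second-difference penalty ``lam`` and asymmetry ``p``).
    """
    if len(s) < 3:
        raise ValueError("baseline correction needs at least 3 points")
    w, a = s.wavenumbers, s.absorbance
    if method == "linear-endpoints":
        base = a[0] + (a[-1] - a[0]) * (w - w[0]) / (w[-1] - w[0])
    elif method == "rubberband":
        base = _rubberband(w, a)
    elif method == "asls":
        base = _asls(a, lam, p, n_iter)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return s.with_absorbance(a - base, f"baseline:{method}")


def band_area(s: Spectrum, lo: float, hi: float) -> float:
    """Trapezoid integral of absorbance over [lo, hi], cm^-1 x absorbance units.

    The window edges are included by linear interpolation, so the value is
    stable under grid refinement.
    """
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    w = s.wavenumbers
    if lo < w[0] or hi > w[-1]:
        raise ValueError(f"grid [{w[0]}, {w[-1]}] does not cover window [{lo}, {hi}]")
    inner = w[(w > lo) & (w < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    return float(np.trapezoid(s.interp(grid), grid))


def normalize_unit_area(s: Spectrum, window: tuple[float, float] = NORMALIZATION_WINDOW) -> Spectrum:
    """Scale the whole spectrum so its trapezoid area over ``window`` equals 1."""
    area = band_area(s, *window)
    if area <= 0:
        raise ValueError(f"non-positive area {area} over window {window}")
    return s.with_absorbance(s.absorbance / area, f"normalize_unit_area:{window}")


def bin_10cm(
    s: Spectrum,
    windows: tuple[tuple[float, float], ...] = BIN_WINDOWS,
    width: float = 10.0,
    stat: str = "integral",
) -> BinnedSpectrum:
    """Summarize absorbance in successive ``width`` cm^-1 bins over ``windows``.

    ``stat``: ``integral`` (trapezoid over the bin, the default), ``mean`` of
    in-bin samples, or ``sum`` of in-bin samples.  Bins not fully covered by
    the grid are flagged missing (NaN value), never silently zero.
    """
    if stat not in ("integral", "mean", "sum"):
        raise ValueError(f"unknown bin stat {stat!r}")
    w = s.wavenumbers
    all_edges, all_vals, all_missing = [], [], []
    for lo, hi in windows:
        edges = np.arange(lo, hi + width / 2, width)
        vals = np.full(edges.size - 1, np.nan)
        missing = np.ones(edges.size - 1, dtype=bool)
        for i, (b0, b1) in enumerate(zip(edges[:-1], edges[1:])):
            if b0 < w[0] or b1 > w[-1]:
                continue
            if stat == "integral":
                vals[i] = band_area(s, b0, b1)
            else:
                last = i == edges.size - 2
                sel = (w >= b0) & ((w <= b1) if last else (w < b1))
                if not sel.any():
                    continue
                vals[i] = s.absorbance[sel].sum() if stat == "sum" else s.absorbance[sel].mean()
            missing[i] = False
        all_edges.append(edges)
        all_vals.append(vals)
        all_missing.append(missing)
    return BinnedSpectrum(tuple(all_edges), tuple(all_vals), tuple(all_missing), stat)


def gsh_band(s: Spectrum, window: tuple[float, float] = GSH_WINDOW) -> float:
    """Integrated absorbance over the S-H stretch window (default 2,540-2,550 cm^-1)."""
    return band_area(s, *window)


def sd_mean_ratio(
    trial: TrialSpectra,
    window: tuple[float, float] = (2450.0, 2800.0),
    grid_step: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise SD/mean across a trial's spectra on a common grid.

    Spectra are linearly interpolated to a ``grid_step`` cm^-1 grid spanning
    ``window``; the ratio uses the n-1 standard deviation and is NaN wherever
    the pointwise mean is zero.  Returns ``(grid, ratio)``.
    """
    if len(trial.spectra) < 2:
        raise ValueError("SD/mean needs at least 2 spectra per trial")
    lo = max(window[0], max(s.wavenumbers[0] for s in trial.spectra))
    hi = min(window[1], min(s.wavenumbers[-1] for s in trial.spectra))
    if lo >= hi:
        raise ValueError("spectra do not jointly cover the requested window")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mat = np.vstack([s.interp(grid) for s in trial.spectra])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean == 0, np.nan, sd / mean)
    return grid, ratio
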