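"""Surface-density mass model and breakage/impurity ratio estimation.

Harvested raw sugarcane arrives at the refinery as a mixture of intact cane,
broken cane, and impurities (tops and leaves).  Given a segmentation of an
overhead image into those four material classes, each class's mass is
estimated from its pixel count through a per-class *surface density* (grams
per pixel), obtained by fitting a Gaussian to the per-sample density
distribution of a calibration set.  The breakage ratio is the mass fraction
of broken cane within all cane, and the impurity ratio is the mass fraction
of tops plus leaves within the whole sample:

    R_B = M_B / (M_C + M_B)
    R_I = (M_T + M_L) / (M_C + M_B + M_T + M_L)

Both ratios are stored as fractions in [0, 1]; rendering as percent is a
presentation concern.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MATERIAL_CLASSES",
    "DEFAULT_SURFACE_DENSITY",
    "MassPixelSample",
    "ClassDensity",
    "SurfaceDensityModel",
    "MassEstimate",
    "RatioPair",
    "RegressionResult",
    "EvaluationReport",
    "UndefinedRatioError",
    "count_class_pixels",
    "fit_surface_density",
    "estimate_mass",
    "estimate_ratios",
    "relative_error",
    "evaluate_ratio_tables",
    "select_confidence_interval",
    "regress_estimated_vs_measured",
    "read_mass_csv",
    "write_mass_csv",
    "read_pairs_csv",
]

#: The four material classes, in canonical order (background is not a
#: material class and carries no mass).
MATERIAL_CLASSES: tuple[str, ...] = ("cane", "broken_cane", "top", "leaf")

#: Reference mean surface densities in g/pixel for cane, broken cane, top
#: and leaf, from Gaussian fits to a 300-sample calibration set.
DEFAULT_SURFACE_DENSITY: dict[str, float] = {
    "cane": 1.52e-3,
    "broken_cane": 7.4e-4,
    "top": 8.8e-4,
    "leaf": 3e-5,
}


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio's denominator is zero (no mass in any class)."""


@dataclass(frozen=True)
class MassPixelSample:
    """Per-image class pixel counts and measured class masses (grams)."""

    sample_id: str
    pixels: Mapping[str, int]
    masses: Mapping[str, float]

    def __post_init__(self) -> None:
        for cls, p in self.pixels.items():
            if int(p) != p or p < 0:
                raise ValueError(f"pixel count for {cls!r} must be a non-negative integer, got {p}")
        for cls, m in self.masses.items():
            if m < 0:
                raise ValueError(f"mass for {cls!r} must be non-negative, got {m}")
            if m > 0 and self.pixels.get(cls, 0) == 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: class {cls!r} has mass {m} g but zero pixels"
                )

    def density(self, cls: str) -> float:
        """Surface density mass/pixels for one class (g/pixel)."""
        p = self.pixels.get(cls, 0)
        if p == 0:
            raise ZeroDivisionError(f"sample {self.sample_id!r} has no {cls!r} pixels")
        return self.masses.get(cls, 0.0) / p


@dataclass(frozen=True)
class ClassDensity:
    """Fitted Gaussian surface density for one class."""

    mu: float  # g/pixel
    sigma: float = 0.0  # g/pixel
    r2: float = 1.0  # agreement between histogram and fitted PDF
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")


@dataclass(frozen=True)
class SurfaceDensityModel:
    """Per-class fitted surface densities.

    ``SurfaceDensityModel.reference()`` returns the calibration constants
    (1.52e-3, 7.4e-4, 8.8e-4, 3e-5 g/pixel) with zero spread.
    """

    classes: Mapping[str, ClassDensity]

    @classmethod
    def reference(cls) -> "SurfaceDensityModel":
        return cls({c: ClassDensity(mu=mu) for c, mu in DEFAULT_SURFACE_DENSITY.items()})

    @classmethod
    def from_mu_sigma(
        cls, mu: Mapping[str, float], sigma: Mapping[str, float] | None = None
    ) -> "SurfaceDensityModel":
        sigma = sigma or {}
        return cls({c: ClassDensity(mu=m, sigma=sigma.get(c, 0.0)) for c, m in mu.items()})

    def mu(self, cls_name: str) -> float:
        return self.classes[cls_name].mu

    def __iter__(self):
        return iter(self.classes)


@dataclass(frozen=True)
class MassEstimate:
    """Estimated per-class masses M' = mu_class * pixel count (grams)."""

    masses: Mapping[str, float]

    def __post_init__(self) -> None:
        for cls, m in self.masses.items():
            if m < 0:
                raise ValueError(f"estimated mass for {cls!r} is negative: {m}")

    def __getitem__(self, cls: str) -> float:
        return self.masses.get(cls, 0.0)

    def total(self) -> float:
        return float(sum(self.masses.values()))


@dataclass(frozen=True)
class RatioPair:
    """Breakage and impurity ratios as fractions in [0, 1]."""

    breakage: float
    impurity: float

    def __post_init__(self) -> None:
        for name, v in (("breakage", self.breakage), ("impurity", self.impurity)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} ratio must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of estimated against measured values with its ANOVA table."""

    slope: float
    intercept: float
    r2: float
    ss_total: float
    ss_regression: float
    ss_residual: float
    df_regression: int
    df_residual: int
    f_statistic: float
    significance: float  # p-value of the F test

    def as_dict(self) -> dict[str, float]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "ss_total": self.ss_total,
            "ss_regression": self.ss_regression,
            "ss_residual": self.ss_residual,
            "df_regression": self.df_regression,
            "df_residual": self.df_residual,
            "f_statistic": self.f_statistic,
            "significance": self.significance,
        }


@dataclass
class EvaluationReport:
    """Per-sample relative errors of a ratio column plus summary statistics."""

    sample_ids: list[str]
    measured: list[float]
    estimated: list[float]
    relative_errors: list[float]
    mean_relative_error: float
    regression: RegressionResult

    def to_json(self) -> str:
        return json.dumps(
            {
                "samples": [
                    {"sample_id": s, "measured": m, "estimated": e, "relative_error": r}
                    for s, m, e, r in zip(
                        self.sample_ids, self.measured, self.estimated, self.relative_errors
                    )
                ],
                "mean_relative_error": self.mean_relative_error,
                "regression": self.regression.as_dict(),
            },
            indent=2,
        )

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "measured", "estimated", "relative_error"])
            for row in zip(self.sample_ids, self.measured, self.estimated, self.relative_errors):
                w.writerow(row)
            w.writerow(["mean", "", "", self.mean_relative_error])


# ---------------------------------------------------------------------------
# pixel counting
# ---------------------------------------------------------------------------

def count_class_pixels(
    mask: np.ndarray, palette: Mapping[str, object]
) -> dict[str, int]:
    """Count pixels per class in a segmentation mask.

    ``mask`` may be a 2-D class-index raster (values are palette indices, in
    the order of ``palette``'s keys) or an RGB raster of shape ``(H, W, 3)``
    whose colors must all appear in ``palette``.  Background is counted and
    reported like any other class; material classes are simply the non-
    background keys.

    Raises ``ValueError`` naming the offending value if the mask contains a
    color or index not in the palette.
    """
    mask = np.asarray(mask)
    names = list(palette.keys())
    counts = {name: 0 for name in names}
    if mask.ndim == 2:
        values, freq = np.unique(mask, return_counts=True)
        for v, f in zip(values, freq):
            if v < 0 or v >= len(names):
                raise ValueError(f"mask contains unknown class index {int(v)}")
            counts[names[int(v)]] = int(f)
    elif mask.ndim == 3 and mask.shape[2] == 3:
        color_to_name = {tuple(int(c) for c in np.ravel(v)): k for k, v in palette.items()}
        flat = mask.reshape(-1, 3)
        colors, freq = np.unique(flat, axis=0, return_counts=True)
        for color, f in zip(colors, freq):
            key = tuple(int(c) for c in color)
            if key not in color_to_name:
                raise ValueError(f"mask contains unknown color {key}")
            counts[color_to_name[key]] = int(f)
    else:
        raise ValueError(f"mask must be HxW indices or HxWx3 RGB, got shape {mask.shape}")
    assert sum(counts.values()) == mask.shape[0] * mask.shape[1]
    return counts


# ---------------------------------------------------------------------------
# Gaussian surface-density fitting
# ---------------------------------------------------------------------------

def _histogram_r2(densities: np.ndarray, mu: float, sigma: float, bins: int) -> float:
    """R² between the normalized frequency histogram and N(mu, sigma) at bin centers."""
    if sigma <= 1e-12 * abs(mu) or np.ptp(densities) <= 1e-12 * abs(mu):
        # degenerate distribution: histogram is a single spike; call it perfect
        return 1.0
    heights, edges = np.histogram(densities, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = stats.norm.pdf(centers, loc=mu, scale=sigma)
    ss_res = float(np.sum((heights - pdf) ** 2))
    ss_tot = float(np.sum((heights - heights.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def fit_surface_density(
    samples: Sequence[MassPixelSample],
    cls: str,
    method: str = "moments",
    bins: int | None = None,
) -> ClassDensity:
    """Fit a Gaussian to the per-sample surface densities of one class.

    Samples with a zero pixel count for ``cls`` are excluded with a warning.
    ``method='moments'`` (default) takes the sample mean and standard
    deviation of the densities; ``method='histogram'`` least-squares fits the
    Gaussian PDF to the normalized frequency histogram.  The fit quality
    ``r2`` always compares the fitted PDF with the normalized histogram at
    bin centers.  ``bins`` defaults to Sturges' rule.
    """
    usable, skipped = [], 0
    for s in samples:
        if s.pixels.get(cls, 0) > 0:
            usable.append(s.masses.get(cls, 0.0) / s.pixels[cls])
        else:
            skipped += 1
    if skipped:
        warnings.warn(
            f"fit_surface_density({cls!r}): excluded {skipped} sample(s) with zero pixel count",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError(
            f"fit_surface_density({cls!r}) needs at least 2 usable samples, got {len(usable)}"
        )
    d = np.asarray(usable, dtype=float)
    n = d.size
    if bins is None:
        bins = int(np.ceil(np.log2(n))) + 1  # Sturges
    mu = float(d.mean())
    sigma = float(d.std(ddof=1))
    if method == "histogram" and sigma > 0:
        heights, edges = np.histogram(d, bins=bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        try:
            (mu, sigma), _ = optimize.curve_fit(
                lambda x, m, s: stats.norm.pdf(x, loc=m, scale=abs(s)),
                centers,
                heights,
                p0=(mu, sigma),
                maxfev=10000,
            )
            mu, sigma = float(mu), float(abs(sigma))
        except RuntimeError:
            warnings.warn(
                f"fit_surface_density({cls!r}): histogram fit did not converge; "
                "falling back to moment estimates",
                stacklevel=2,
            )
    elif method not in ("moments", "histogram"):
        raise ValueError(f"unknown method {method!r}; use 'moments' or 'histogram'")
    r2 = _histogram_r2(d, mu, sigma, bins)
    return ClassDensity(mu=mu, sigma=sigma, r2=r2, n_samples=n)


def fit_surface_density_model(
    samples: Sequence[MassPixelSample],
    classes: Sequence[str] = MATERIAL_CLASSES,
    **kwargs,
) -> SurfaceDensityModel:
    """Fit all material classes at once; see :func:`fit_surface_density`."""
    return SurfaceDensityModel({c: fit_surface_density(samples, c, **kwargs) for c in classes})


# ---------------------------------------------------------------------------
# mass and ratio estimation
# ---------------------------------------------------------------------------

def estimate_mass(
    pixels: Mapping[str, int], density: SurfaceDensityModel | None = None
) -> MassEstimate:
    """Estimate per-class mass (grams) as mu_class x pixel count.

    With the reference densities, 100000 cane pixels weigh 152 g.
    """
    if density is None:
        density = SurfaceDensityModel.reference()
    masses = {}
    for cls in density:
        p = pixels.get(cls, 0)
        if p < 0:
            raise ValueError(f"negative pixel count for {cls!r}: {p}")
        masses[cls] = density.mu(cls) * p
    return MassEstimate(masses)


def estimate_ratios(masses: MassEstimate | Mapping[str, float]) -> RatioPair:
    """Breakage and impurity ratios from per-class masses (measured or estimated).

    breakage = M_B / (M_C + M_B); impurity = (M_T + M_L) / total mass.
    A zero denominator raises :class:`UndefinedRatioError` rather than
    producing NaN.
    """
    m = masses.masses if isinstance(masses, MassEstimate) else masses
    mc = m.get("cane", 0.0)
    mb = m.get("broken_cane", 0.0)
    mt = m.get("top", 0.0)
    ml = m.get("leaf", 0.0)
    cane_total = mc + mb
    total = mc + mb + mt + ml
    if total == 0:
        raise UndefinedRatioError("all class masses are zero; ratios are undefined")
    breakage = 0.0 if mb == 0 else mb / cane_total
    impurity = 0.0 if (mt + ml) == 0 else (mt + ml) / total
    return RatioPair(breakage=breakage, impurity=impurity)


def relative_error(measured: float, estimated: float) -> float:
    """|measured - estimated| / measured, as a fraction."""
    if measured <= 0:
        raise ValueError(f"measured value must be positive, got {measured}")
    if estimated < 0:
        raise ValueError(f"estimated value must be non-negative, got {estimated}")
    return abs(measured - estimated) / measured


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

def regress_estimated_vs_measured(
    pairs: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS regression of estimated on measured values with an ANOVA table.

    The total sum of squares decomposes into regression + residual with
    degrees of freedom (1, n-2); significance is the upper-tail p-value of
    F = MS_reg / MS_res.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs for regression, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("measured values are constant; regression is degenerate")
    fit = stats.linregress(x, y)
    yhat = fit.intercept + fit.slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_reg = float(np.sum((yhat - y.mean()) ** 2))
    df_reg, df_res = 1, len(pairs) - 2
    if ss_res > 0 and df_res > 0:
        f_stat = (ss_reg / df_reg) / (ss_res / df_res)
        sig = float(stats.f.sf(f_stat, df_reg, df_res))
    else:
        f_stat, sig = math.inf, 0.0
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        ss_total=ss_tot,
        ss_regression=ss_reg,
        ss_residual=ss_res,
        df_regression=df_reg,
        df_residual=df_res,
        f_statistic=float(f_stat),
        significance=sig,
    )


def evaluate_ratio_tables(
    pairs: Sequence[tuple[float, float]],
    sample_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Per-sample relative errors, their mean, and the estimated-vs-measured fit.

    ``pairs`` are (measured, estimated) ratio fractions.  The mean is the
    arithmetic mean of the unrounded per-sample relative errors.
    """
    if len(pairs) == 0:
        raise ValueError("evaluate_ratio_tables needs at least one (measured, estimated) pair")
    ids = list(sample_ids) if sample_ids is not None else [str(i + 1) for i in range(len(pairs))]
    errors = [relative_error(m, e) for m, e in pairs]
    if len(pairs) >= 3 and np.ptp([p[0] for p in pairs]) > 0:
        reg = regress_estimated_vs_measured(pairs)
    else:  # too few points for a meaningful fit; report a degenerate identity
        reg = RegressionResult(
            slope=float("nan"), intercept=float("nan"), r2=0.0,
            ss_total=0.0, ss_regression=0.0, ss_residual=0.0,
            df_regression=1, df_residual=max(0, len(pairs) - 2),
            f_statistic=float("nan"), significance=float("nan"),
        )
    return EvaluationReport(
        sample_ids=ids,
        measured=[p[0] for p in pairs],
        estimated=[p[1] for p in pairs],
        relative_errors=errors,
        mean_relative_error=float(np.mean(errors)),
        regression=reg,
    )


def select_confidence_interval(
    samples: Sequence[MassPixelSample],
    level: float = 0.95,
    model: SurfaceDensityModel | None = None,
) -> list[MassPixelSample]:
    """Keep samples whose surface densities lie inside the central CI per class.

    For each class present in a sample (pixels > 0), the sample's density
    must fall within mu +/- z(level) * sigma of that class's fitted Gaussian;
    a sample is dropped if any present class falls outside (marginal
    filtering).  ``model`` defaults to a moment fit on ``samples`` itself.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if model is None:
        model = fit_surface_density_model(samples)
    z = stats.norm.ppf(0.5 + level / 2.0)
    kept = []
    for s in samples:
        ok = True
        for cls in model:
            if s.pixels.get(cls, 0) == 0:
                continue
            cd = model.classes[cls]
            if cd.sigma == 0:
                continue
            if abs(s.density(cls) - cd.mu) > z * cd.sigma:
                ok = False
                break
        if ok:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_mass_csv(path) -> list[MassPixelSample]:
    """Read a long-format mass table: sample_id, class, pixels, mass_g."""
    by_id: dict[str, dict[str, dict[str, float]]] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "class", "pixels", "mass_g"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns {sorted(required)}")
        for row in reader:
            cls = row["class"]
            if cls not in MATERIAL_CLASSES:
                raise ValueError(f"{path}: unknown class {cls!r}")
            sid = row["sample_id"]
            if sid not in by_id:
                by_id[sid] = {"pixels": {}, "masses": {}}
                order.append(sid)
            by_id[sid]["pixels"][cls] = int(row["pixels"])
            by_id[sid]["masses"][cls] = float(row["mass_g"])
    return [
        MassPixelSample(sample_id=sid, pixels=by_id[sid]["pixels"], masses=by_id[sid]["masses"])
        for sid in order
    ]


def write_mass_csv(samples: Iterable[MassPixelSample], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "class", "pixels", "mass_g"])
        for s in samples:
            for cls in MATERIAL_CLASSES:
                if cls in s.pixels or cls in s.masses:
                    w.writerow([s.sample_id, cls, s.pixels.get(cls, 0), s.masses.get(cls, 0.0)])


def read_pairs_csv(path) -> tuple[list[str], list[tuple[float, float]]]:
    """Read a (measured, estimated) pairs table: sample_id, measured, estimated."""
    ids, pairs = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "measured", "estimated"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns {sorted(required)}")
        for row in reader:
            ids.append(row["sample_id"])
            pairs.append((float(row["measured"]), float(row["estimated"])))
    return ids, pairs
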