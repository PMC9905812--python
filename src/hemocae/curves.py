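"""Synthetic thrombin-generation (thrombinogram) dose-response datasets.

A thrombin generation assay measures the concentration of thrombin in a
plasma sample over time.  The resulting curve -- the thrombinogram -- shows a
lag phase, a rise to a peak and an exponential tail; in hemophilia A the peak
height is inversely related to disease severity, and therapeutic factor VIII
(FVIII) restores the peak toward normal with a saturating dose response.

This module generates datasets of ``{x, c, y}`` triplets emulating an
in-vitro dose-titration study: ``x`` is a patient's baseline (dose-0)
thrombinogram, ``c`` a normalized FVIII dose in [0, 1] and ``y`` the
post-treatment thrombinogram.  Triplets are grouped by plasma (patient) and
split into train/validation/test at the plasma level so that no plasma leaks
across splits.

Curve family
------------
Each plasma is described by a latent :class:`PlasmaPhenotype`.  The clean
curve is a gamma-variate: zero during the lag, then

    f(t) = u(t)^alpha * exp(alpha * (1 - u(t))),   u(t) = (t - lag) / (tp - lag)

which rises from 0 at ``t = lag`` to 1 at the time-to-peak ``tp`` and decays
with tail time-constant ``decay = (tp - lag) / alpha``.  The sampled shape is
rescaled so that its discrete maximum equals the dose-dependent peak height

    peak(c) = severity + (1 - severity) * c^s / (c^s + k^s)

(a Hill-type saturating response with half-maximal dose ``k`` and slope
``s``); the lag shortens proportionally to the same response.  At ``c = 0``
the peak equals ``severity``, so severe phenotypes produce flat baselines.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError

__all__ = [
    "Thrombinogram",
    "PlasmaPhenotype",
    "Triplet",
    "TripletDataset",
    "sample_phenotype",
    "generate_curve",
    "generate_dataset",
    "dose_to_percent",
]

#: Half-maximal normalized dose of the saturating FVIII response.
HILL_K = 0.5

DEFAULT_T = 180
DEFAULT_TIME_STEP_MIN = 1.0 / 3.0  # three measurements per minute
DEFAULT_NOISE_SD = 0.01
DEFAULT_DOSE_SCALE_PCT = 125.0
DEFAULT_DOSES_PER_PLASMA = 17


@dataclass(frozen=True)
class Thrombinogram:
    """A normalized thrombin-concentration time course.

    Parameters
    ----------
    values : ndarray of shape (T,)
        Thrombin concentration, unitless, each value in [0, 1].
    time_step_min : float
        Minutes between consecutive samples.
    """

    values: np.ndarray
    time_step_min: float = DEFAULT_TIME_STEP_MIN

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 4:
            raise ParameterError("a thrombinogram needs at least 4 samples")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ParameterError("thrombinogram values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_min(self) -> float:
        return len(self) * self.time_step_min

    @property
    def peak_height(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class PlasmaPhenotype:
    """Latent generative factors of one plasma (patient).

    severity : scalar in (0, 1], baseline peak height; low = severe disease.
    lag_min, ttpeak_min, decay_min : curve timing parameters, minutes.
    dose_sensitivity : Hill slope of the dose response (> 0).
    """

    severity: float
    lag_min: float
    ttpeak_min: float
    decay_min: float
    dose_sensitivity: float

    def __post_init__(self):
        if not (0 < self.severity <= 1):
            raise ParameterError("severity must be in (0, 1]")
        if not (0 <= self.lag_min < self.ttpeak_min):
            raise ParameterError("need 0 <= lag_min < ttpeak_min")
        if self.decay_min <= 0 or self.dose_sensitivity <= 0:
            raise ParameterError("decay_min and dose_sensitivity must be > 0")


@dataclass(frozen=True)
class Triplet:
    """One (baseline curve, dose, post-treatment curve) record."""

    x: Thrombinogram
    c: float
    y: Thrombinogram
    plasma_id: str

    def __post_init__(self):
        if len(self.x) != len(self.y):
            raise ParameterError("x and y must have equal length")
        if not (0 <= self.c <= 1):
            raise ParameterError("dose c must lie in [0, 1]")


def _hill(c, s):
    c = np.asarray(c, dtype=float)
    return np.where(c > 0, c**s / (c**s + HILL_K**s), 0.0)


def dose_to_percent(c: float, dose_scale_pct: float = DEFAULT_DOSE_SCALE_PCT) -> float:
    """Convert a normalized dose ``c`` in [0, 1] to percent FVIII (linear map)."""
    if not (0 <= c <= 1):
        raise ParameterError(f"dose c={c} outside [0, 1]")
    return float(c * dose_scale_pct)


def sample_phenotype(
    rng_seed: int,
    severity_range: tuple[float, float] = (0.05, 0.4),
) -> PlasmaPhenotype:
    """Draw one plasma phenotype; deterministic given ``rng_seed``.

    ``severity_range`` is sampled uniformly; the default spans severe to
    moderate hemophilia-A-like baselines.  Timing parameters span the
    morphological variability seen across thrombinograms: lag 2-8 min,
    rise 3-10 min, tail time-constant 2-8 min.
    """
    lo, hi = severity_range
    if not (0 < lo <= hi <= 1):
        raise ParameterError("severity_range must be a sub-interval of (0, 1]")
    rng = np.random.default_rng(rng_seed)
    severity = float(rng.uniform(lo, hi))
    lag = float(rng.uniform(2.0, 8.0))
    rise = float(rng.uniform(3.0, 10.0))
    decay = float(rng.uniform(2.0, 8.0))
    sens = float(rng.uniform(0.8, 2.0))
    return PlasmaPhenotype(
        severity=severity,
        lag_min=lag,
        ttpeak_min=lag + rise,
        decay_min=decay,
        dose_sensitivity=sens,
    )


def _clean_curve(pheno: PlasmaPhenotype, c: float, T: int, time_step_min: float) -> np.ndarray:
    """Noise-free curve sampled on the time grid; discrete max == peak(c)."""
    r = float(_hill(c, pheno.dose_sensitivity))
    peak = pheno.severity + (1.0 - pheno.severity) * r
    lag = pheno.lag_min * (1.0 - 0.5 * r)  # dose shortens the lag
    tp = lag + (pheno.ttpeak_min - pheno.lag_min)
    alpha = max((tp - lag) / pheno.decay_min, 0.5)
    t = np.arange(T) * time_step_min
    u = np.clip((t - lag) / (tp - lag), 0.0, None)
    with np.errstate(divide="ignore"):
        shape = np.where(u > 0, u**alpha * np.exp(alpha * (1.0 - u)), 0.0)
    m = shape.max()
    if m <= 0:  # peak falls beyond the observation window
        return np.zeros(T)
    return peak * shape / m


def generate_curve(
    pheno: PlasmaPhenotype,
    c: float,
    T: int = DEFAULT_T,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed: int = 0,
    time_step_min: float = DEFAULT_TIME_STEP_MIN,
) -> Thrombinogram:
    """Thrombinogram of ``pheno`` after dose ``c``, with additive noise.

    At ``noise_sd = 0`` the peak height is non-decreasing in ``c`` (the
    discrete shape is rescaled to the analytic dose-dependent peak) and
    ``c = 0`` reproduces the baseline curve exactly.
    """
    if not (0 <= c <= 1):
        raise ParameterError(f"dose c={c} outside [0, 1]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if T < 4:
        raise ParameterError("curve length T must be >= 4")
    v = _clean_curve(pheno, c, T, time_step_min)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        v = v + rng.normal(0.0, noise_sd, size=T)
    return Thrombinogram(np.clip(v, 0.0, 1.0), time_step_min)


@dataclass
class TripletDataset:
    """Plasma-grouped triplets with train/val/test splits.

    Arrays are row-aligned: ``x``/``y`` have shape (N, T), ``c`` shape (N,),
    ``plasma_id`` and ``split`` shape (N,) of strings.  ``split_of`` maps
    each plasma to its split; splits are disjoint at the plasma level.
    """

    x: np.ndarray
    c: np.ndarray
    y: np.ndarray
    plasma_id: np.ndarray
    split: np.ndarray
    dose_scale_pct: float = DEFAULT_DOSE_SCALE_PCT
    time_step_min: float = DEFAULT_TIME_STEP_MIN
    split_of: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.c)
        if not (self.x.shape[0] == self.y.shape[0] == n == len(self.plasma_id) == len(self.split)):
            raise DataError("row counts disagree across dataset arrays")
        if self.x.shape != self.y.shape:
            raise DataError("x and y must have the same shape")
        if not self.split_of:
            self.split_of = {
                str(p): str(s) for p, s in zip(self.plasma_id, self.split)
            }
        seen: dict[str, str] = {}
        for p, s in zip(self.plasma_id, self.split):
            if seen.setdefault(str(p), str(s)) != str(s):
                raise DataError(f"plasma {p} appears in two splits")
        for name in ("train", "val", "test"):
            if name not in set(map(str, self.split)):
                raise DataError(f"split '{name}' is empty")

    def __len__(self) -> int:
        return len(self.c)

    @property
    def T(self) -> int:
        return self.x.shape[1]

    def subset(self, split: str) -> "TripletDataset":
        mask = self.split == split
        if not mask.any():
            raise DataError(f"no triplets in split '{split}'")
        # bypass __post_init__: a single-split view legitimately lacks the others
        ds = object.__new__(TripletDataset)
        ds.x = self.x[mask]
        ds.c = self.c[mask]
        ds.y = self.y[mask]
        ds.plasma_id = self.plasma_id[mask]
        ds.split = self.split[mask]
        ds.dose_scale_pct = self.dose_scale_pct
        ds.time_step_min = self.time_step_min
        ds.split_of = {p: s for p, s in self.split_of.items() if s == split}
        return ds

    def arrays(self, split: str | None = None):
        """Return (x, c, y) arrays, optionally restricted to one split."""
        if split is None:
            return self.x, self.c, self.y
        m = self.split == split
        return self.x[m], self.c[m], self.y[m]

    def sklearn_arrays(self, split: str | None = None):
        """Return ``(X, y, groups)`` in the packed estimator convention.

        ``X`` stacks the baseline curve and the dose as its last column;
        ``groups`` are the plasma ids (for group-aware splitting).
        """
        x, c, y = self.arrays(split)
        mask = slice(None) if split is None else self.split == split
        X = np.concatenate([x, c[:, None]], axis=1)
        return X, y, self.plasma_id[mask]

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w", track_order=True) as f:
            for name, arr in (("x", self.x), ("y", self.y), ("c", self.c)):
                f.create_dataset(name, data=np.asarray(arr, dtype=float), track_times=False)
            st = h5py.string_dtype()
            f.create_dataset("plasma_id", data=self.plasma_id.astype(object), dtype=st, track_times=False)
            f.create_dataset("split", data=self.split.astype(object), dtype=st, track_times=False)
            f.attrs["dose_scale_pct"] = self.dose_scale_pct
            f.attrs["time_step_min"] = self.time_step_min

    @classmethod
    def from_hdf5(cls, path: str) -> "TripletDataset":
        with h5py.File(path, "r") as f:
            return cls(
                x=f["x"][...],
                c=f["c"][...],
                y=f["y"][...],
                plasma_id=f["plasma_id"].asstr()[...],
                split=f["split"].asstr()[...],
                dose_scale_pct=float(f.attrs["dose_scale_pct"]),
                time_step_min=float(f.attrs["time_step_min"]),
            )

    def to_dataframe(self) -> pd.DataFrame:
        T = self.T
        cols = {
            "plasma_id": self.plasma_id,
            "split": self.split,
            "c": self.c,
        }
        df = pd.DataFrame(cols)
        xdf = pd.DataFrame(self.x, columns=[f"x_{i}" for i in range(T)])
        ydf = pd.DataFrame(self.y, columns=[f"y_{i}" for i in range(T)])
        return pd.concat([df, xdf, ydf], axis=1)

    def to_csv(self, path: str) -> None:
        # %.10g keeps files compact yet round-trips well below curve noise
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str, dose_scale_pct: float = DEFAULT_DOSE_SCALE_PCT,
                 time_step_min: float = DEFAULT_TIME_STEP_MIN) -> "TripletDataset":
        df = pd.read_csv(path)
        xcols = sorted((c for c in df.columns if c.startswith("x_")), key=lambda s: int(s[2:]))
        ycols = sorted((c for c in df.columns if c.startswith("y_")), key=lambda s: int(s[2:]))
        return cls(
            x=df[xcols].to_numpy(float),
            c=df["c"].to_numpy(float),
            y=df[ycols].to_numpy(float),
            plasma_id=df["plasma_id"].to_numpy(str),
            split=df["split"].to_numpy(str),
            dose_scale_pct=dose_scale_pct,
            time_step_min=time_step_min,
        )

    def csv_bytes(self) -> bytes:
        buf = _io.StringIO()
        self.to_dataframe().to_csv(buf, index=False, float_format="%.10g")
        return buf.getvalue().encode()


def generate_dataset(
    n_plasmas: tuple[int, int, int] = (73, 19, 23),
    doses_per_plasma: int = DEFAULT_DOSES_PER_PLASMA,
    T: int = DEFAULT_T,
    rng_seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    severity_range: tuple[float, float] = (0.05, 0.4),
    dose_scale_pct: float = DEFAULT_DOSE_SCALE_PCT,
    time_step_min: float = DEFAULT_TIME_STEP_MIN,
) -> TripletDataset:
    """Generate a plasma-grouped dose-titration dataset.

    Every plasma contributes ``doses_per_plasma`` triplets at doses
    ``i / doses_per_plasma`` for ``i = 1..doses_per_plasma`` (spread over
    (0, 1]); ``x`` is the plasma's dose-0 curve, reused across its triplets.
    Clean curves are normalized by the global maximum over the whole dataset
    before noise is added, so the across-dose peak-height ordering survives
    normalization.  Fully deterministic given ``rng_seed``.
    """
    n_train, n_val, n_test = n_plasmas
    if min(n_train, n_val, n_test) < 1:
        raise ParameterError("each split needs at least one plasma")
    if doses_per_plasma < 1:
        raise ParameterError("doses_per_plasma must be >= 1")
    if T < 4:
        raise ParameterError("curve length T must be >= 4")

    n_total = n_train + n_val + n_test
    root = np.random.SeedSequence(rng_seed)
    pheno_seeds, noise_seed = root.spawn(2)
    noise_rng = np.random.default_rng(noise_seed)

    split_names = (
        ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    )
    doses = np.arange(1, doses_per_plasma + 1) / doses_per_plasma

    ids, splits, cs = [], [], []
    xs, ys = [], []
    for i, child in enumerate(pheno_seeds.spawn(n_total)):
        pheno = sample_phenotype(child, severity_range=severity_range)
        x0 = _clean_curve(pheno, 0.0, T, time_step_min)
        pid = f"P{i:03d}"
        for c in doses:
            ids.append(pid)
            splits.append(split_names[i])
            cs.append(float(c))
            xs.append(x0)
            ys.append(_clean_curve(pheno, float(c), T, time_step_min))

    x = np.asarray(xs)
    y = np.asarray(ys)
    gmax = max(x.max(), y.max())
    if gmax > 0:
        x = x / gmax
        y = y / gmax
    if noise_sd > 0:
        # the baseline is measured once per plasma: one noise draw per
        # plasma, reused across its triplets; y is a fresh assay per dose
        x_noise = noise_rng.normal(0.0, noise_sd, size=(n_total, T))
        x = x + np.repeat(x_noise, doses_per_plasma, axis=0)
        y = y + noise_rng.normal(0.0, noise_sd, size=y.shape)
    x = np.clip(x, 0.0, 1.0)
    y = np.clip(y, 0.0, 1.0)

    return TripletDataset(
        x=x,
        c=np.asarray(cs),
        y=y,
        plasma_id=np.asarray(ids, dtype=object).astype(str),
        split=np.asarray(splits, dtype=object).astype(str),
        dose_scale_pct=dose_scale_pct,
        time_step_min=time_step_min,
    )
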