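"""Illuminant-adapted oxygenation regression.

The downstream consumer of light source calibration: an ensemble
(random-forest) regressor maps an L1-normalized 16-band measurement of
tissue to the oxygenation ``sox`` of the shallowest layer.  Because the
normalized measurement depends on the illuminant, a regressor is trained
per illuminant; at run time the regressor whose training illuminant is
angularly closest to the current calibration estimate is selected.

Measurements here use the narrow-band factorization

    ``I_k = alpha * w_k * ell_k * rho_k``

where ``ell_k`` is the band-space illuminant (the quantity calibration
estimates) and ``rho_k`` the band-averaged tissue reflectance.  For the
15 nm-wide Gaussian bands of the camera model this is an excellent
approximation of the full spectral integral, and it lets estimated (band
space) and reference illuminants enter the experiment on an equal
footing.  The per-sample gain ``alpha`` cancels under L1 normalization.

The mismatch experiment quantifies the benefit of calibration: test sets
are rendered under each reference illuminant, and the oxygenation error
is compared between regressors trained under the matched illuminant, a
mismatched one, and the calibrated estimate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core import IlluminantSpectrum, WavelengthGrid, angular_error, l1_normalize
from .errors import ConfigurationError, DegenerateInputError, DimensionError
from .tissue import (
    CameraModel,
    ChromophoreTable,
    NoiseModel,
    TissueRanges,
    TissueSample,
    reflectance_matrix,
    sample_tissue,
)

__all__ = [
    "LabeledSpectra",
    "RegressorBank",
    "BankEntry",
    "ExperimentDesign",
    "ExperimentResult",
    "build_training_set",
    "train_regressor",
    "select_regressor",
    "evaluate_oxygenation",
    "run_illuminant_mismatch_experiment",
    "train_bank",
    "save_bank",
    "load_bank",
]

DEFAULT_ALPHA_RANGE = (0.1, 10.0)
MIN_TRAINING_ROWS = 100


@dataclass(frozen=True)
class LabeledSpectra:
    """Normalized band measurements with oxygenation labels."""

    X: np.ndarray  # (n, n_bands), rows sum to 1
    y: np.ndarray  # (n,), sox in [0, 1]
    illuminant_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise DimensionError("X must be (n, bands) aligned with y")
        if np.any(np.abs(X.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("rows of X must be L1-normalized")
        if np.any((y < 0) | (y > 1)):
            raise ConfigurationError("labels must lie in [0, 1]")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.X.shape[0]


class OxygenationRegressor:
    """Random-forest ensemble with predictions clipped to [0, 1]."""

    def __init__(self, forest: RandomForestRegressor):
        self._forest = forest

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self._forest.predict(np.asarray(X, dtype=float)), 0.0, 1.0)


@dataclass(frozen=True)
class BankEntry:
    illuminant_id: str
    spectrum: IlluminantSpectrum  # band-space, L1-normalized
    regressor: OxygenationRegressor


@dataclass(frozen=True)
class RegressorBank:
    """Illuminant-indexed regressors; ids must be unique."""

    entries: tuple[BankEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.illuminant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("bank illuminant ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)


def save_bank(bank: RegressorBank, directory) -> None:
    """Serialize a bank to a directory: ``manifest.json`` with the illuminant
    spectra inline plus one joblib file per trained regressor."""
    import json
    from pathlib import Path

    import joblib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, entry in enumerate(bank.entries):
        fname = f"regressor_{k:02d}.joblib"
        joblib.dump(entry.regressor, directory / fname)
        manifest.append(
            dict(
                illuminant_id=entry.illuminant_id,
                spectrum=list(entry.spectrum.values),
                file=fname,
            )
        )
    (directory / "manifest.json").write_text(json.dumps({"entries": manifest}, indent=1))


def load_bank(directory) -> RegressorBank:
    import json
    from pathlib import Path

    import joblib

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    entries = []
    for item in manifest["entries"]:
        entries.append(
            BankEntry(
                illuminant_id=item["illuminant_id"],
                spectrum=IlluminantSpectrum(
                    l1_normalize(np.asarray(item["spectrum"])), normalized=True
                ),
                regressor=joblib.load(directory / item["file"]),
            )
        )
    return RegressorBank(tuple(entries))


def train_bank(
    illuminants: dict[str, IlluminantSpectrum],
    grid: WavelengthGrid,
    camera: CameraModel,
    n_train: int = 2000,
    seed: int = 0,
    noise: NoiseModel | None = None,
    table: ChromophoreTable | None = None,
    n_estimators: int = 100,
    ranges: TissueRanges | None = None,
) -> RegressorBank:
    """Train one oxygenation regressor per band-space illuminant."""
    noise = noise if noise is not None else NoiseModel()
    table = table or ChromophoreTable.default()
    rng = np.random.default_rng(seed)
    samples = sample_tissue(n_train, rng, ranges or TissueRanges())
    rho = band_reflectance(samples, grid, camera, table)
    entries = []
    for name in sorted(illuminants):
        spectrum = illuminants[name].as_normalized()
        data = build_training_set(
            samples, spectrum, grid, camera, noise, rng,
            table=table, illuminant_id=name, band_rho=rho,
        )
        entries.append(
            BankEntry(name, spectrum, train_regressor(data, n_estimators=n_estimators, seed=seed))
        )
    return RegressorBank(tuple(entries))


@dataclass(frozen=True)
class ExperimentDesign:
    """Sizes, illuminants and seeds of the mismatch experiment.

    ``illuminants`` maps id to the band-space illuminant; ``estimates`` is a
    list of (test illuminant id, band-space estimate) pairs, typically the
    output of running calibration on simulated scenes of that illuminant.
    """

    illuminants: dict[str, IlluminantSpectrum]
    estimates: tuple[tuple[str, IlluminantSpectrum], ...] = ()
    n_train: int = 10_000
    n_test: int = 5_000
    seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    ranges: TissueRanges = field(default_factory=TissueRanges)
    n_estimators: int = 100
    min_samples_leaf: int = 5

    def __post_init__(self) -> None:
        if len(self.illuminants) < 1:
            raise ConfigurationError("experiment needs at least one illuminant")
        for test_id, _ in self.estimates:
            if test_id not in self.illuminants:
                raise ConfigurationError(f"estimate references unknown illuminant {test_id!r}")

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test


@dataclass(frozen=True)
class ExperimentResult:
    """Per-condition MAE table plus aggregate summary."""

    table: pd.DataFrame  # columns: test_ls, condition, train_ls, mae_pp
    summary: dict

    def reductions(self) -> pd.DataFrame:
        return self.table


def band_reflectance(
    samples: list[TissueSample],
    grid: WavelengthGrid,
    camera: CameraModel,
    table: ChromophoreTable,
) -> np.ndarray:
    """Band-averaged reflectance ``rho`` per sample, shape (n, n_bands)."""
    xi = camera.band_responses(grid)
    w = grid.trapezoid_weights()
    kernel = (xi * w[None, :]).T  # (n_wl, n_bands)
    norm = xi @ w
    r = reflectance_matrix(samples, grid, table)
    return (r @ kernel) / norm[None, :]


def build_training_set(
    samples: list[TissueSample],
    illuminant: IlluminantSpectrum | np.ndarray,
    grid: WavelengthGrid,
    camera: CameraModel,
    noise: NoiseModel,
    rng: np.random.Generator | int,
    table: ChromophoreTable | None = None,
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
    illuminant_id: str = "",
    band_rho: np.ndarray | None = None,
) -> LabeledSpectra:
    """Render tissue samples to normalized band measurements under an illuminant.

    ``illuminant`` is a band-space spectrum (length ``camera.n_bands``);
    labels are the first-layer oxygenation.  The same samples under
    different illuminants yield the same labels and different features.
    ``band_rho`` can carry precomputed band reflectances to avoid
    re-rendering the same samples for every illuminant.
    """
    if len(samples) == 0:
        raise ConfigurationError("no tissue samples given")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = table or ChromophoreTable.default()
    ell = np.asarray(
        illuminant.values if isinstance(illuminant, IlluminantSpectrum) else illuminant,
        dtype=float,
    )
    if ell.shape != (camera.n_bands,):
        raise DimensionError(
            f"band-space illuminant must have length {camera.n_bands}; got {ell.shape}"
        )
    rho = band_rho if band_rho is not None else band_reflectance(samples, grid, camera, table)
    alpha = rng.uniform(*alpha_range, size=len(samples))
    measurements = alpha[:, None] * ell[None, :] * rho
    measurements = measurements * noise.draw(measurements.shape, rng)
    sums = measurements.sum(axis=1)
    if np.any(sums <= 0):  # noise clipped an entire row to zero; re-floor
        raise DegenerateInputError("a rendered measurement vanished entirely")
    X = measurements / sums[:, None]
    y = np.array([s.oxygenation for s in samples])
    return LabeledSpectra(X=X, y=y, illuminant_id=illuminant_id)


def train_regressor(
    train: LabeledSpectra,
    n_estimators: int = 100,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> OxygenationRegressor:
    """Fit the random-forest ensemble; deterministic for a fixed seed."""
    if len(train) < MIN_TRAINING_ROWS:
        raise ConfigurationError(
            f"need at least {MIN_TRAINING_ROWS} training rows; got {len(train)}"
        )
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train.X, train.y)
    return OxygenationRegressor(forest)


def select_regressor(bank: RegressorBank, estimate: IlluminantSpectrum) -> BankEntry:
    """Bank entry whose illuminant is angularly closest to the estimate;
    exact ties resolve to the lowest illuminant id."""
    if len(bank) == 0:
        raise ConfigurationError("empty regressor bank")
    scored = [
        (angular_error(entry.spectrum, estimate), entry.illuminant_id, entry)
        for entry in bank.entries
    ]
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2]


def evaluate_oxygenation(regressor: OxygenationRegressor, test: LabeledSpectra) -> float:
    """Mean absolute oxygenation error in percentage points."""
    if len(test) == 0:
        raise ConfigurationError("empty test set")
    pred = regressor.predict(test.X)
    return float(np.mean(np.abs(pred - test.y)) * 100.0)


def run_illuminant_mismatch_experiment(
    design: ExperimentDesign,
    grid: WavelengthGrid | None = None,
    camera: CameraModel | None = None,
    table: ChromophoreTable | None = None,
) -> ExperimentResult:
    """Matched / mismatched / calibrated comparison.

    All training sets share the same ground-truth tissue samples (only the
    illuminant changes); likewise the test sets.  Conditions:

    - ``matched``: train and test under the same reference illuminant.
    - ``mismatched``: train under each *other* reference illuminant.
    - ``calibrated``: train under a calibration estimate of the test
      illuminant (one regressor per estimate).

    The summary reports per-condition mean MAE and the mean relative
    error reduction of calibration, ``(1 - MAE_cal / MAE_mis) * 100``,
    averaged over test illuminants.
    """
    grid = grid or WavelengthGrid.default()
    camera = camera or CameraModel()
    table = table or ChromophoreTable.default()
    rng = np.random.default_rng(design.seed)

    samples = sample_tissue(design.n_total, rng, design.ranges)
    train_samples = samples[: design.n_train]
    test_samples = samples[design.n_train :]
    rho_train = band_reflectance(train_samples, grid, camera, table)
    rho_test = band_reflectance(test_samples, grid, camera, table)

    def make_set(samples_, rho, ell, label, split):
        # the rendering noise stream depends only on (seed, split, illuminant),
        # so an estimate identical to a reference illuminant yields the
        # identical data set
        values = np.asarray(
            ell.values if isinstance(ell, IlluminantSpectrum) else ell, dtype=np.float64
        )
        digest = hashlib.sha256(np.ascontiguousarray(values).tobytes()).digest()
        words = [int(w) for w in np.frombuffer(digest[:16], dtype=np.uint32)]
        set_rng = np.random.default_rng(
            np.random.SeedSequence([design.seed, split, *words])
        )
        return build_training_set(
            samples_, ell, grid, camera, design.noise, set_rng,
            table=table, illuminant_id=label, band_rho=rho,
        )

    ids = list(design.illuminants)
    train_sets = {i: make_set(train_samples, rho_train, design.illuminants[i], i, 0) for i in ids}
    test_sets = {i: make_set(test_samples, rho_test, design.illuminants[i], i, 1) for i in ids}

    rf_kwargs = dict(
        n_estimators=design.n_estimators,
        min_samples_leaf=design.min_samples_leaf,
        seed=design.seed,
    )
    regressors = {i: train_regressor(train_sets[i], **rf_kwargs) for i in ids}

    rows = []
    for test_id in ids:
        rows.append(
            dict(
                test_ls=test_id,
                condition="matched",
                train_ls=test_id,
                mae_pp=evaluate_oxygenation(regressors[test_id], test_sets[test_id]),
            )
        )
        for train_id in ids:
            if train_id == test_id:
                continue
            rows.append(
                dict(
                    test_ls=test_id,
                    condition="mismatched",
                    train_ls=train_id,
                    mae_pp=evaluate_oxygenation(regressors[train_id], test_sets[test_id]),
                )
            )
    for k, (test_id, estimate) in enumerate(design.estimates):
        reg = train_regressor(
            make_set(train_samples, rho_train, estimate, f"estimate_{k}", 0), **rf_kwargs
        )
        rows.append(
            dict(
                test_ls=test_id,
                condition="calibrated",
                train_ls=f"estimate_{k}",
                mae_pp=evaluate_oxygenation(reg, test_sets[test_id]),
            )
        )

    df = pd.DataFrame(rows)
    summary: dict = {}
    for condition in ("matched", "mismatched", "calibrated"):
        sub = df[df.condition == condition]
        if len(sub):
            summary[f"{condition}_mean_pp"] = float(sub.mae_pp.mean())
    per_ls = []
    for test_id in ids:
        mis = df[(df.test_ls == test_id) & (df.condition == "mismatched")].mae_pp
        cal = df[(df.test_ls == test_id) & (df.condition == "calibrated")].mae_pp
        if len(mis) and len(cal):
            per_ls.append(
                dict(
                    test_ls=test_id,
                    mismatched_pp=float(mis.mean()),
                    calibrated_pp=float(cal.mean()),
                    reduction_pct=float((1.0 - cal.mean() / mis.mean()) * 100.0),
                )
            )
    if per_ls:
        summary["per_test_ls"] = per_ls
        summary["mean_reduction_pct"] = float(
            np.mean([p["reduction_pct"] for p in per_ls])
        )
    return ExperimentResult(table=df, summary=summary)
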