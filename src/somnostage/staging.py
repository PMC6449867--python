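"""Epoch feature assembly, stage-system mapping and the LD classifier.

The classifier follows the classic Gaussian linear discriminant with a
pooled within-class covariance: every 30-s epoch is described by 30
features (13 respiratory + 13 cardiac + 4 movement) and assigned the
class k maximizing

    delta_k(x) = x' S^-1 mu_k - 1/2 mu_k' S^-1 mu_k + log pi_k

where S is the pooled covariance shrunk toward its diagonal,
S* = (1 - lambda) S + lambda diag(S), mu_k the class means and pi_k the
priors.  Features are standardized by training-set location/scale (no
per-subject normalization).  The estimator is scikit-learn compatible
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import StagingConfig
from .io_core import DataError, EpochGrid, Hypnogram, STAGE_ALPHABETS
from .respiratory import RESP_FEATURE_NAMES
from .cardiac import CARDIAC_FEATURE_NAMES
from .movement import MOVEMENT_FEATURE_NAMES

__all__ = [
    "EpochFeatureMatrix",
    "StageSystem",
    "STAGE_SYSTEMS",
    "LinearDiscriminantStager",
    "assemble_features",
    "map_stages",
    "train_ld",
    "predict_stages",
    "save_model",
    "load_model",
    "FEATURE_NAMES",
]

FEATURE_NAMES = RESP_FEATURE_NAMES + CARDIAC_FEATURE_NAMES + MOVEMENT_FEATURE_NAMES


@dataclass
class EpochFeatureMatrix:
    """n_epochs x 30 feature matrix with per-cell imputation flags."""

    values: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    imputed_flags: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.feature_names):
            raise DataError(
                f"feature matrix has {self.values.shape[1]} columns, "
                f"expected {len(self.feature_names)}"
            )
        if self.imputed_flags is None:
            self.imputed_flags = np.zeros(self.values.shape, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class StageSystem:
    """A reduced staging alphabet and its mapping from raw AASM labels."""

    id: str
    classes: tuple[str, ...]
    raw_mapping: dict[str, str]


STAGE_SYSTEMS: dict[str, StageSystem] = {
    # 2-stage: wake vs sleep (REM and all NREM pooled)
    "s2": StageSystem(
        "s2",
        ("W", "S"),
        {"W": "W", "REM": "S", "N1": "S", "N2": "S", "N3": "S"},
    ),
    # 3-stage: wake / REM / NREM
    "s3": StageSystem(
        "s3",
        ("W", "REM", "NREM"),
        {"W": "W", "REM": "REM", "N1": "NREM", "N2": "NREM", "N3": "NREM"},
    ),
    # 4-stage: wake / REM / light sleep (N1+N2) / deep sleep (N3)
    "s4": StageSystem(
        "s4",
        ("W", "REM", "LS", "DS"),
        {"W": "W", "REM": "REM", "N1": "LS", "N2": "LS", "N3": "DS"},
    ),
}


def map_stages(h: Hypnogram, system: StageSystem | str) -> Hypnogram:
    """Relabel a raw hypnogram into a reduced staging system.

    Idempotent on hypnograms already in the target alphabet.
    """
    if isinstance(system, str):
        system = STAGE_SYSTEMS[system]
    if h.alphabet_id == system.id:
        return Hypnogram(list(h.labels), system.id)
    if h.alphabet_id != "raw":
        raise DataError(
            f"cannot map {h.alphabet_id!r} hypnogram into system {system.id!r}"
        )
    try:
        labels = [system.raw_mapping[l] for l in h.labels]
    except KeyError as exc:
        raise DataError(f"label {exc.args[0]!r} has no mapping in {system.id}") from exc
    return Hypnogram(labels, system.id)


def assemble_features(
    resp_block: np.ndarray,
    card_block: np.ndarray,
    move_block: np.ndarray,
    grid: EpochGrid,
    subject_id: str = "",
) -> EpochFeatureMatrix:
    """Concatenate the three per-epoch blocks into the 30-feature matrix.

    NaN cells (degenerate epochs) are imputed with the recording median
    of that feature and flagged; a feature that is NaN for the whole
    recording is imputed with 0.
    """
    blocks = [np.atleast_2d(b) for b in (resp_block, card_block, move_block)]
    for b, width in zip(blocks, (13, 13, 4)):
        if b.shape != (grid.n_epochs, width):
            raise DataError(
                f"feature block shape {b.shape} does not match grid "
                f"({grid.n_epochs} epochs x {width})"
            )
    values = np.hstack(blocks)
    flags = ~np.isfinite(values)
    if flags.any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(np.where(np.isfinite(values), values, np.nan), axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        values = np.where(flags, med[None, :], values)
    return EpochFeatureMatrix(values, imputed_flags=flags, subject_id=subject_id)


class LinearDiscriminantStager(BaseEstimator, ClassifierMixin):
    """Gaussian linear discriminant for sleep-stage classification.

    Parameters
    ----------
    shrinkage : float in [0, 1]
        Diagonal shrinkage of the pooled covariance,
        ``S* = (1 - shrinkage) S + shrinkage diag(S)``; stabilizes the
        estimate when rare stages (N3) contribute few epochs.
    priors : {"empirical", "uniform"}
        Class priors from training frequencies, or flat.
    tie_break : str
        Class preferred on exact discriminant ties (then training class
        order).

    Attributes
    ----------
    classes_ : ndarray of class labels
    class_means_ : (n_classes, n_features) means in normalized space
    covariance_ : (n_features, n_features) shrunk pooled covariance
    priors_ : class priors, summing to 1
    loc_, scale_ : per-feature normalization from the training data
    """

    def __init__(
        self,
        shrinkage: float = 0.1,
        priors: str = "empirical",
        tie_break: str = "W",
    ):
        self.shrinkage = shrinkage
        self.priors = priors
        self.tie_break = tie_break

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must be in [0, 1]")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError(
                f"training data contains a single class {classes.tolist()}; "
                "at least 2 are required"
            )
        self.loc_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z = (X - self.loc_) / self.scale_

        n, p = Z.shape
        means = np.empty((classes.size, p))
        pooled = np.zeros((p, p))
        counts = np.empty(classes.size)
        for k in range(classes.size):
            zk = Z[y_idx == k]
            counts[k] = zk.shape[0]
            means[k] = zk.mean(axis=0)
            d = zk - means[k]
            pooled += d.T @ d
        dof = max(1, n - classes.size)
        pooled /= dof
        lam = self.shrinkage
        cov = (1 - lam) * pooled + lam * np.diag(np.diag(pooled))
        # diagonal zeros (constant features) would make S singular
        diag = np.diag(cov).copy()
        fix = diag <= 0
        if fix.any():
            cov[fix, fix] = 1.0
        try:
            self.precision_ = np.linalg.inv(cov)
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "pooled covariance singular despite shrinkage"
            ) from exc
        self.covariance_ = cov
        self.class_means_ = means
        self.classes_ = classes
        if self.priors == "uniform":
            self.priors_ = np.full(classes.size, 1.0 / classes.size)
        else:
            self.priors_ = counts / counts.sum()
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        """Discriminant scores delta_k(x) for every class."""
        check_is_fitted(self, "classes_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        Z = (X - self.loc_) / self.scale_
        W = self.precision_ @ self.class_means_.T  # (p, K)
        const = -0.5 * np.einsum("kp,pk->k", self.class_means_, W) + np.log(
            self.priors_
        )
        return Z @ W + const

    def predict(self, X):
        delta = self.decision_function(X)
        # ties prefer tie_break class, then earlier class order
        order = np.arange(self.classes_.size)
        pref = np.flatnonzero(self.classes_ == self.tie_break)
        if pref.size:
            order = np.concatenate([pref, order[order != pref[0]]])
        best = delta[:, order].argmax(axis=1)  # argmax keeps first on ties
        return self.classes_[order[best]]

    def predict_proba(self, X):
        """Posterior class probabilities (softmax of the discriminants)."""
        return softmax(self.decision_function(X), axis=1)

    def to_dict(self) -> dict:
        check_is_fitted(self, "classes_")
        return {
            "classes": self.classes_.tolist(),
            "class_means": self.class_means_.tolist(),
            "covariance": self.covariance_.tolist(),
            "priors": self.priors_.tolist(),
            "loc": self.loc_.tolist(),
            "scale": self.scale_.tolist(),
            "shrinkage": self.shrinkage,
            "tie_break": self.tie_break,
            "feature_names": list(FEATURE_NAMES)
            if self.n_features_in_ == len(FEATURE_NAMES)
            else [],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LinearDiscriminantStager":
        model = cls(shrinkage=data["shrinkage"], tie_break=data["tie_break"])
        model.classes_ = np.asarray(data["classes"])
        model.class_means_ = np.asarray(data["class_means"], dtype=float)
        model.covariance_ = np.asarray(data["covariance"], dtype=float)
        model.priors_ = np.asarray(data["priors"], dtype=float)
        model.loc_ = np.asarray(data["loc"], dtype=float)
        model.scale_ = np.asarray(data["scale"], dtype=float)
        model.precision_ = np.linalg.inv(model.covariance_)
        model.n_features_in_ = model.loc_.size
        return model


def save_model(model: LinearDiscriminantStager, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path) -> LinearDiscriminantStager:
    with open(path) as fh:
        return LinearDiscriminantStager.from_dict(json.load(fh))


def train_ld(
    matrices: list[EpochFeatureMatrix],
    hypnograms: list[Hypnogram],
    system: StageSystem | str,
    cfg: StagingConfig | None = None,
    require_all_classes: bool = True,
) -> LinearDiscriminantStager:
    """Train the LD classifier on a cohort, in the requested stage system.

    Raw hypnograms are mapped into the system first.  With
    ``require_all_classes`` every class of the system must appear in the
    pooled training epochs (error names the missing class).
    """
    if isinstance(system, str):
        system = STAGE_SYSTEMS[system]
    cfg = cfg or StagingConfig()
    X = np.vstack([m.values for m in matrices])
    y: list[str] = []
    for m, h in zip(matrices, hypnograms):
        mapped = map_stages(h, system)
        if m.n_epochs != mapped.n_epochs:
            raise DataError(
                f"subject {m.subject_id!r}: {m.n_epochs} feature epochs vs "
                f"{mapped.n_epochs} hypnogram epochs"
            )
        y.extend(mapped.labels)
    present = set(y)
    missing = [c for c in system.classes if c not in present]
    if missing and require_all_classes:
        raise ValueError(f"class {missing[0]!r} absent from training data")
    model = LinearDiscriminantStager(
        shrinkage=cfg.shrinkage, priors=cfg.priors, tie_break="W"
    )
    return model.fit(X, np.asarray(y))


def predict_stages(
    model: LinearDiscriminantStager,
    X: EpochFeatureMatrix,
    system_id: str | None = None,
    median_filter_epochs: int = 0,
) -> tuple[Hypnogram, np.ndarray]:
    """Predict a hypnogram and per-class posteriors for one recording.

    An optional odd-length median filter smooths the predicted label
    sequence (off by default; the reference chain uses none).
    """
    labels = model.predict(X.values)
    posteriors = model.predict_proba(X.values)
    if median_filter_epochs and median_filter_epochs > 1:
        k = median_filter_epochs | 1  # force odd
        classes = list(model.classes_)
        codes = np.array([classes.index(l) for l in labels])
        from scipy.signal import medfilt

        labels = np.asarray(classes)[medfilt(codes, k).astype(int)]
    if system_id is None:
        system_id = next(
            (s.id for s in STAGE_SYSTEMS.values() if set(s.classes) >= set(model.classes_)),
            "raw",
        )
    return Hypnogram(list(labels), system_id), posteriors
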