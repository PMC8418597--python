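"""Pixel-intensity logistic-regression tumor classification.

A single-feature logistic regression maps raw fluorescence intensity to
tumor probability:  p = sigmoid(b0 + b1 * (x - center) / scale).  Intensity
is standardized for numerical stability but thresholds are always reported
back on the raw count scale, matching the convention of quoting an operating
point like 1.43e4 counts on a 16-bit camera.

Two validation protocols are provided:

* image-wise — a stratified random 70 % of each image's labeled pixels
  trains a per-image model; ROC analysis on the held-out 30 % yields AUC,
  the Youden operating point, and sensitivity/specificity.
* leave-one-image-out — each image is scored by a model trained on the
  pooled labeled pixels of all remaining images.

``PixelLogit`` / ``PixelLogitResults`` expose the model in the familiar
model-object idiom (construct from data, ``fit()``, ``summary()``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dataio import Case, extract_pixel_samples
from .exceptions import ConvergenceWarning
from .stats import ROCCurve, optimal_threshold, roc_curve

__all__ = [
    "LogisticModel",
    "ValidationScore",
    "PixelLogit",
    "PixelLogitResults",
    "fit_logistic",
    "split_ground_truth",
    "validate_image_wise",
    "validate_loocv",
    "invert_threshold",
    "render_overlay",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class LogisticModel:
    """Fitted single-feature logistic regression on standardized intensity.

    ``beta0``/``beta1`` act on the standardized intensity
    (x - center) / scale; ``bse`` are Wald standard errors from the inverse
    penalized Hessian.  Predictions are deterministic functions of the
    stored coefficients.
    """

    beta0: float
    beta1: float
    center: float
    scale: float
    ridge: float
    converged: bool
    n_iter: int
    bse: tuple[float, float] = (float("nan"), float("nan"))

    def standardize(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    def predict_proba(self, x) -> np.ndarray:
        return _sigmoid(self.beta0 + self.beta1 * self.standardize(x))

    @property
    def raw_coefficients(self) -> tuple[float, float]:
        """(intercept, slope) acting directly on raw counts."""
        b1 = self.beta1 / self.scale
        return self.beta0 - self.beta1 * self.center / self.scale, b1


@dataclass
class ValidationScore:
    """Per-image validation outcome under one protocol."""

    image_id: str
    scheme: str  # "image_wise" | "loocv"
    auc: float
    probability_threshold: float
    intensity_threshold: float
    sensitivity: float
    specificity: float
    n_train_px: int = 0
    n_val_px: int = 0
    cohort: str = ""


def fit_logistic(
    intensities,
    labels,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Fit a ridge-penalized logistic regression of tumor label on intensity.

    Maximizes the Bernoulli log-likelihood minus ``ridge * beta1**2`` (the
    slope only; the intercept is unpenalized) by Newton iteration with
    step-halving, on intensity standardized by its training mean and SD.
    Convergence when the largest coefficient change falls below ``tol``;
    hitting ``max_iter`` emits :class:`ConvergenceWarning` and flags the
    returned model.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("intensities and labels must be equal-length and non-empty")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    center = float(x.mean())
    scale = float(x.std())
    if scale == 0.0:
        raise ValueError("intensity is constant; no classifier exists")
    xs = (x - center) / scale

    beta = np.zeros(2)

    def penalized_loglik(b):
        z = b[0] + b[1] * xs
        # log-likelihood via log1p(exp(.)) stable form
        ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
        return ll - ridge * b[1] ** 2

    ll_old = penalized_loglik(beta)
    converged = False
    n_iter = 0
    hess = np.eye(2)
    for n_iter in range(1, max_iter + 1):
        z = beta[0] + beta[1] * xs
        p = _sigmoid(z)
        w = p * (1.0 - p)
        grad = np.array([np.sum(y - p), np.sum((y - p) * xs) - 2.0 * ridge * beta[1]])
        hess = np.array(
            [
                [np.sum(w), np.sum(w * xs)],
                [np.sum(w * xs), np.sum(w * xs * xs) + 2.0 * ridge],
            ]
        )
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad / max(hess[0, 0], 1e-12)
        # step-halving on the penalized objective
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            if penalized_loglik(cand) >= ll_old - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll_new = penalized_loglik(beta)
        if np.max(np.abs(t * step)) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    if not converged:
        warnings.warn(
            f"logistic fit did not converge in {max_iter} iterations", ConvergenceWarning
        )
    try:
        cov = np.linalg.inv(hess)
        bse = (float(math.sqrt(max(cov[0, 0], 0.0))), float(math.sqrt(max(cov[1, 1], 0.0))))
    except np.linalg.LinAlgError:
        bse = (float("nan"), float("nan"))
    return LogisticModel(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        center=center,
        scale=scale,
        ridge=ridge,
        converged=converged,
        n_iter=n_iter,
        bse=bse,
    )


def split_ground_truth(
    labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split of labeled pixels into train/validation indices.

    Within each class, ``round(train_fraction * n_class)`` pixels train and
    the rest validate; the two index sets are disjoint and exhaustive.
    """
    y = np.asarray(labels).ravel()
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 pixels; cannot split")
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both splits non-empty
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        val_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(val_parts))


def invert_threshold(model: LogisticModel, p_star: float) -> float:
    """Raw-count intensity at which predicted tumor probability equals p_star.

    For positive slope, pixels above the returned intensity have
    probability above ``p_star``.
    """
    if model.beta1 == 0.0:
        raise ValueError("slope is zero; no intensity threshold exists")
    if not 0.0 < p_star < 1.0:
        raise ValueError("p_star must be strictly inside (0, 1)")
    logit = math.log(p_star / (1.0 - p_star))
    return model.center + model.scale * (logit - model.beta0) / model.beta1


def _score_validation(
    model: LogisticModel,
    x_val: np.ndarray,
    y_val: np.ndarray,
    image_id: str,
    scheme: str,
    n_train: int,
    cohort: str = "",
) -> ValidationScore:
    probs = model.predict_proba(x_val)
    curve = roc_curve(probs[y_val == 1], probs[y_val == 0])
    p_star, sens, spec = optimal_threshold(curve)
    # map back to the raw count scale; fall back to +/-inf for a saturated p*
    if 0.0 < p_star < 1.0 and model.beta1 != 0.0:
        x_star = invert_threshold(model, p_star)
        # p* is an observed pixel's probability; snap the inverse back onto
        # that pixel's intensity so the raw-count rule matches exactly
        j = int(np.argmin(np.abs(x_val - x_star)))
        if abs(float(x_val[j]) - x_star) <= 1e-6 * max(1.0, abs(x_star)):
            x_star = float(x_val[j])
    else:
        x_star = float("-inf") if model.beta1 >= 0 else float("inf")
    return ValidationScore(
        image_id=image_id,
        scheme=scheme,
        auc=curve.auc,
        probability_threshold=p_star,
        intensity_threshold=x_star,
        sensitivity=sens,
        specificity=spec,
        n_train_px=n_train,
        n_val_px=int(x_val.size),
        cohort=cohort,
    )


def _case_pixels(case: Case) -> tuple[np.ndarray, np.ndarray]:
    tumor, healthy = extract_pixel_samples(case.image, case.mask)
    x = np.concatenate([tumor, healthy])
    y = np.concatenate([np.ones(tumor.size), np.zeros(healthy.size)])
    return x, y


def validate_image_wise(
    case: Case,
    train_fraction: float = 0.7,
    ridge: float = 1e-6,
    seed: int = 0,
) -> tuple[ValidationScore, LogisticModel]:
    """Train on a stratified 70 % of one image's labeled pixels, validate on
    the held-out 30 %, and report the Youden operating point."""
    x, y = _case_pixels(case)
    train_idx, val_idx = split_ground_truth(y, train_fraction=train_fraction, seed=seed)
    model = fit_logistic(x[train_idx], y[train_idx], ridge=ridge)
    score = _score_validation(
        model,
        x[val_idx],
        y[val_idx],
        image_id=case.image_id,
        scheme="image_wise",
        n_train=int(train_idx.size),
        cohort=case.patient.cohort,
    )
    return score, model


def validate_loocv(
    cases: list[Case], ridge: float = 1e-6
) -> tuple[list[ValidationScore], list[LogisticModel]]:
    """Leave-one-image-out validation over a list of cases.

    For each held-out image the model trains on the pooled labeled pixels of
    every other image (standardization comes from that pooled training set)
    and is scored on all labeled pixels of the held-out image.
    """
    if len(cases) < 2:
        raise ValueError("leave-one-out validation needs at least 2 cases")
    pixel_sets = [_case_pixels(c) for c in cases]
    scores: list[ValidationScore] = []
    models: list[LogisticModel] = []
    for i, case in enumerate(cases):
        x_train = np.concatenate([pixel_sets[j][0] for j in range(len(cases)) if j != i])
        y_train = np.concatenate([pixel_sets[j][1] for j in range(len(cases)) if j != i])
        model = fit_logistic(x_train, y_train, ridge=ridge)
        x_val, y_val = pixel_sets[i]
        scores.append(
            _score_validation(
                model,
                x_val,
                y_val,
                image_id=case.image_id,
                scheme="loocv",
                n_train=int(x_train.size),
                cohort=case.patient.cohort,
            )
        )
        models.append(model)
    return scores, models


def render_overlay(
    case: Case,
    model: LogisticModel,
    intensity_threshold: float,
    overlay_path=None,
    suppressed_path=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-color tumor-probability overlay plus a suppressed fluorescence
    image.

    The suppressed image zeroes every pixel below the intensity threshold.
    The overlay alpha-blends green into the color photograph (or a grayscale
    rendering when no color image exists) in proportion to predicted tumor
    probability, for supra-threshold pixels only.
    """
    fluor = np.asarray(case.image.pixels)
    supra = fluor.astype(float) >= intensity_threshold
    suppressed = np.where(supra, fluor, 0).astype(fluor.dtype)

    if case.color is not None:
        base = np.asarray(case.color, dtype=float).copy()
    else:
        import logging

        logging.getLogger(__name__).warning(
            "no color image for %s; overlay drawn on grayscale rendering", case.image_id
        )
        ceiling = float(2**case.image.bit_depth - 1)
        gray = fluor.astype(float) / ceiling * 255.0
        base = np.stack([gray] * 3, axis=-1)

    probs = model.predict_proba(fluor)
    alpha = np.where(supra, probs, 0.0)
    overlay = base.copy()
    overlay[..., 1] = (1.0 - alpha) * base[..., 1] + alpha * 255.0
    overlay = np.clip(np.rint(overlay), 0, 255).astype(np.uint8)

    if suppressed_path is not None:
        from .dataio import write_fluorescence

        write_fluorescence(suppressed_path, replace_pixels(case.image, suppressed))
    if overlay_path is not None:
        from .dataio import write_color

        write_color(overlay_path, overlay)
    return overlay, suppressed


def replace_pixels(image, pixels):
    from .dataio import FluorescenceImage

    return FluorescenceImage(
        pixels,
        bit_depth=image.bit_depth,
        pixel_scale_mm=image.pixel_scale_mm,
        acquisition_context=image.acquisition_context,
    )


# ---------------------------------------------------------------------------
# model-object surface


class PixelLogit:
    """Pixel-intensity logistic tumor classifier, model-object style.

    Construct from (intensity, label) arrays or from a case via
    :meth:`from_case`; ``fit()`` returns :class:`PixelLogitResults`.
    """

    def __init__(self, intensities, labels, ridge: float = 1e-6):
        self.intensities = np.asarray(intensities, dtype=float).ravel()
        self.labels = np.asarray(labels, dtype=float).ravel()
        self.ridge = ridge

    @classmethod
    def from_case(cls, case: Case, ridge: float = 1e-6) -> "PixelLogit":
        x, y = _case_pixels(case)
        return cls(x, y, ridge=ridge)

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "PixelLogitResults":
        model = fit_logistic(
            self.intensities, self.labels, ridge=self.ridge, max_iter=max_iter, tol=tol
        )
        return PixelLogitResults(self, model)


class PixelLogitResults:
    """Fitted classifier: coefficients, uncertainties, and diagnostics."""

    def __init__(self, model_spec: PixelLogit, model: LogisticModel):
        self.model_spec = model_spec
        self.model = model
        self.nobs = int(model_spec.intensities.size)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.model.beta0, self.model.beta1])

    @property
    def bse(self) -> np.ndarray:
        return np.array(self.model.bse)

    def predict(self, x=None) -> np.ndarray:
        x = self.model_spec.intensities if x is None else x
        return self.model.predict_proba(x)

    def intensity_threshold(self, p_star: float = 0.5) -> float:
        return invert_threshold(self.model, p_star)

    def training_roc(self) -> ROCCurve:
        probs = self.predict()
        y = self.model_spec.labels
        return roc_curve(probs[y == 1], probs[y == 0])

    def summary(self) -> str:
        m = self.model
        roc = self.training_roc()
        lines = [
            "Pixel-intensity logistic regression",
            "=" * 54,
            f"{'n pixels':<28}{self.nobs:>26d}",
            f"{'converged':<28}{str(m.converged):>26}",
            f"{'iterations':<28}{m.n_iter:>26d}",
            f"{'ridge (slope penalty)':<28}{m.ridge:>26.3g}",
            f"{'intensity center (counts)':<28}{m.center:>26.2f}",
            f"{'intensity scale (counts)':<28}{m.scale:>26.2f}",
            "-" * 54,
            f"{'':<12}{'coef':>14}{'std err':>14}",
            f"{'intercept':<12}{m.beta0:>14.4f}{m.bse[0]:>14.4f}",
            f"{'slope':<12}{m.beta1:>14.4f}{m.bse[1]:>14.4f}",
            "-" * 54,
            f"{'training AUC':<28}{roc.auc:>26.4f}",
            f"{'intensity @ p=0.5 (counts)':<28}{self.intensity_threshold(0.5):>26.1f}",
        ]
        return "\n".join(lines)
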