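"""Dependent logistic calibration of detection confidences.

The calibrator models the feature vectors s of correct (z = 1) and incorrect
(z = 0) predictions as two multivariate Gaussians and maps a prediction to a
calibrated confidence through the sigmoid of their log-likelihood ratio:

    lr(s) = 1/2 [ (s - mu_minus)^T Sigma_minus^-1 (s - mu_minus)
                - (s - mu_plus)^T  Sigma_plus^-1  (s - mu_plus) ] + c

    c = 1/2 ln(det Sigma_minus / det Sigma_plus) + ln(n_plus / n_minus)

    g(s) = 1 / (1 + exp(-lr(s)))

The "+" population is the correct predictions. With the prior log-odds term
included, lr is the exact Gaussian class-posterior log-odds, so g(s)
converges to P(z = 1 | s) when the class-conditional feature distributions
really are Gaussian. Features are any subset of {confidence, normalized
box-center x, normalized box-center y}; confidence is logit-transformed by
default, since a Gaussian fits an unbounded score far better than one pinned
to [0,1]. Taking the box center along with the confidence lets the map
correct position-dependent overconfidence that a score-only calibrator
cannot see.

Quadratic terms cancel when the two covariances are equal, making lr affine
in s — the familiar logistic/LDA special case; with unequal covariances the
map is the QDA posterior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg

from .detection_io import CalibrationRecord, Detection

FEATURE_NAMES = ("conf", "cx", "cy")

PARAMS_FORMAT_VERSION = 1


class FittingError(ValueError):
    """Raised when a fitting population is too small or degenerate."""


@dataclass(frozen=True)
class FeatureSpec:
    """Which features enter the calibrator, in which order.

    ``logit_conf`` applies the logit transform to the confidence after
    clipping it to [eps, 1 - eps].
    """

    features: tuple[str, ...] = ("conf", "cx", "cy")
    logit_conf: bool = True
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise ValueError("at least one feature required")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate features: {self.features}")
        unknown = [f for f in self.features if f not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown features {unknown}; allowed: {FEATURE_NAMES}")
        if not (0.0 < self.eps < 0.1):
            raise ValueError(f"eps must be in (0, 0.1), got {self.eps}")

    @property
    def dim(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class SplitProtocol:
    """Fit/test partition of prediction records (default 60% to fit)."""

    fit_fraction: float = 0.6
    seed: int = 0
    stratify_by_z: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.fit_fraction < 1.0):
            raise ValueError(f"fit_fraction must be in (0,1), got {self.fit_fraction}")


@dataclass
class CalibratorParams:
    """Fitted two-Gaussian calibrator; fully serializable to JSON."""

    feature_spec: FeatureSpec
    mu_plus: np.ndarray
    mu_minus: np.ndarray
    sigma_plus: np.ndarray
    sigma_minus: np.ndarray
    c: float
    regularization: float
    n_plus: int
    n_minus: int
    include_prior: bool = True

    def __post_init__(self) -> None:
        d = self.feature_spec.dim
        self.mu_plus = np.asarray(self.mu_plus, dtype=float).reshape(d)
        self.mu_minus = np.asarray(self.mu_minus, dtype=float).reshape(d)
        self.sigma_plus = np.asarray(self.sigma_plus, dtype=float).reshape(d, d)
        self.sigma_minus = np.asarray(self.sigma_minus, dtype=float).reshape(d, d)
        # cached Cholesky factors for stable solves (no explicit inverses)
        self._chol_plus = linalg.cho_factor(self.sigma_plus, lower=True)
        self._chol_minus = linalg.cho_factor(self.sigma_minus, lower=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": PARAMS_FORMAT_VERSION,
            "features": list(self.feature_spec.features),
            "logit_conf": self.feature_spec.logit_conf,
            "eps": self.feature_spec.eps,
            "mu_plus": self.mu_plus.tolist(),
            "mu_minus": self.mu_minus.tolist(),
            "sigma_plus": self.sigma_plus.tolist(),
            "sigma_minus": self.sigma_minus.tolist(),
            "c": self.c,
            "regularization": self.regularization,
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "include_prior": self.include_prior,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibratorParams":
        p = json.loads(Path(path).read_text())
        spec = FeatureSpec(tuple(p["features"]), bool(p["logit_conf"]), float(p["eps"]))
        return cls(
            feature_spec=spec,
            mu_plus=np.array(p["mu_plus"]),
            mu_minus=np.array(p["mu_minus"]),
            sigma_plus=np.array(p["sigma_plus"]),
            sigma_minus=np.array(p["sigma_minus"]),
            c=float(p["c"]),
            regularization=float(p["regularization"]),
            n_plus=int(p["n_plus"]),
            n_minus=int(p["n_minus"]),
            include_prior=bool(p["include_prior"]),
        )


def _logit(p: np.ndarray, eps: float) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def build_feature_vector(record: CalibrationRecord, spec: FeatureSpec) -> np.ndarray:
    """Assemble the feature vector s for one record, in spec order."""
    values = {"conf": record.confidence, "cx": record.cx_norm, "cy": record.cy_norm}
    s = np.array([values[f] for f in spec.features], dtype=float)
    if spec.logit_conf and "conf" in spec.features:
        i = spec.features.index("conf")
        s[i] = _logit(np.array(s[i]), spec.eps)
    return s


def build_feature_matrix(
    records: Sequence[CalibrationRecord], spec: FeatureSpec
) -> np.ndarray:
    conf = np.asarray([r.confidence for r in records], dtype=float)
    cols = {
        "conf": _logit(conf, spec.eps) if spec.logit_conf else conf,
        "cx": np.asarray([r.cx_norm for r in records], dtype=float),
        "cy": np.asarray([r.cy_norm for r in records], dtype=float),
    }
    return np.column_stack([cols[f] for f in spec.features])


def fit_gaussian_lr(
    X: np.ndarray,
    z: np.ndarray,
    spec: FeatureSpec,
    regularization: float | None = None,
    include_prior: bool = True,
) -> CalibratorParams:
    """Fit the two-population Gaussian log-likelihood-ratio model.

    ``X`` is the (n, d) feature matrix, ``z`` the 0/1 correctness labels.
    Each population needs at least d + 1 samples (sample covariance with
    denominator n - 1 must exist). ``regularization`` adds lam·I to each
    covariance; default lam = 1e-6 · trace(Sigma)/d, enough to guarantee
    positive-definiteness for near-degenerate populations.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(z)
    if not np.isfinite(X).all():
        raise FittingError("non-finite feature values")
    d = spec.dim
    if X.ndim != 2 or X.shape[1] != d:
        raise FittingError(f"feature matrix must be (n, {d}), got {X.shape}")
    Xp, Xm = X[z == 1], X[z == 0]
    min_n = d + 1
    for name, pop in (("correct (z=1)", Xp), ("incorrect (z=0)", Xm)):
        if len(pop) < min_n:
            raise FittingError(
                f"{name} population has {len(pop)} samples; need >= {min_n} "
                f"for a {d}-dimensional covariance"
            )
    mu_p, mu_m = Xp.mean(axis=0), Xm.mean(axis=0)
    sig_p = np.cov(Xp, rowvar=False).reshape(d, d)
    sig_m = np.cov(Xm, rowvar=False).reshape(d, d)
    if regularization is None:
        regularization = 1e-6 * float(np.trace(sig_p) + np.trace(sig_m)) / (2 * d)
    sig_p = sig_p + regularization * np.eye(d)
    sig_m = sig_m + regularization * np.eye(d)

    # stable log-determinants from Cholesky factors
    logdet_p = 2.0 * np.sum(np.log(np.diag(linalg.cholesky(sig_p, lower=True))))
    logdet_m = 2.0 * np.sum(np.log(np.diag(linalg.cholesky(sig_m, lower=True))))
    c = 0.5 * (logdet_m - logdet_p)
    if include_prior:
        c += math.log(len(Xp) / len(Xm))

    return CalibratorParams(
        feature_spec=spec,
        mu_plus=mu_p,
        mu_minus=mu_m,
        sigma_plus=sig_p,
        sigma_minus=sig_m,
        c=float(c),
        regularization=float(regularization),
        n_plus=len(Xp),
        n_minus=len(Xm),
        include_prior=include_prior,
    )


def fit_dependent_logistic(
    records: Sequence[CalibrationRecord],
    spec: FeatureSpec = FeatureSpec(),
    regularization: float | None = None,
    include_prior: bool = True,
) -> CalibratorParams:
    """Fit the calibrator from matched prediction records."""
    X = build_feature_matrix(records, spec)
    z = np.asarray([r.z for r in records])
    return fit_gaussian_lr(X, z, spec, regularization, include_prior)


def log_likelihood_ratio(params: CalibratorParams, s: np.ndarray) -> np.ndarray:
    """Evaluate lr(s) for one vector (d,) or a batch (n, d)."""
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    S = np.atleast_2d(s)
    d = params.feature_spec.dim
    if S.shape[1] != d:
        raise ValueError(f"feature dimension {S.shape[1]} != fitted dimension {d}")
    dp = S - params.mu_plus
    dm = S - params.mu_minus
    # Mahalanobis terms via Cholesky solves; never form an inverse
    qp = np.einsum("ij,ij->i", dp, linalg.cho_solve(params._chol_plus, dp.T).T)
    qm = np.einsum("ij,ij->i", dm, linalg.cho_solve(params._chol_minus, dm.T).T)
    lr = 0.5 * (qm - qp) + params.c
    return float(lr[0]) if single else lr


def calibration_map(params: CalibratorParams, s: np.ndarray) -> np.ndarray:
    """g(s) = sigmoid(lr(s)), the calibrated confidence."""
    lr = log_likelihood_ratio(params, s)
    out = 1.0 / (1.0 + np.exp(-np.asarray(lr, dtype=float)))
    return float(out) if np.ndim(lr) == 0 else out


def apply_calibration(
    params: CalibratorParams,
    items: Sequence[CalibrationRecord] | Sequence[Detection],
    image_sizes: dict[str, tuple[int, int]] | None = None,
) -> list:
    """Return the same items with ``calibrated_confidence`` filled in.

    Accepts calibration records directly, or detections (then ``image_sizes``
    mapping image_id -> (width, height) is required to normalize box centers).
    The original confidence is preserved alongside.
    """
    if len(items) == 0:
        return []
    if isinstance(items[0], CalibrationRecord):
        records = list(items)
    else:
        if any(f in params.feature_spec.features for f in ("cx", "cy")) and image_sizes is None:
            raise ValueError("image_sizes required to derive box-center features for detections")
        records = []
        for det in items:
            w, h = image_sizes[det.image_id] if image_sizes else (1, 1)
            cx, cy = det.box.center
            records.append(
                CalibrationRecord(
                    det.image_id, det.class_id, det.confidence,
                    min(max(cx / w, 0.0), 1.0), min(max(cy / h, 0.0), 1.0), 0,
                )
            )
    X = build_feature_matrix(records, params.feature_spec)
    g = calibration_map(params, X)
    g = np.atleast_1d(g)
    return [item.with_calibrated(float(v)) for item, v in zip(items, g)]


def split_fit_test(
    records: Sequence[CalibrationRecord], protocol: SplitProtocol = SplitProtocol()
) -> tuple[list[CalibrationRecord], list[CalibrationRecord]]:
    """Seeded disjoint, exhaustive fit/test partition; optionally stratified by z."""
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(protocol.seed)
    if protocol.stratify_by_z:
        fit_idx: list[int] = []
        test_idx: list[int] = []
        for zval in (0, 1):
            idx = [i for i, r in enumerate(records) if r.z == zval]
            rng.shuffle(idx)
            k = int(round(protocol.fit_fraction * len(idx)))
            fit_idx.extend(idx[:k])
            test_idx.extend(idx[k:])
    else:
        idx = list(range(n))
        rng.shuffle(idx)
        k = int(round(protocol.fit_fraction * n))
        fit_idx, test_idx = idx[:k], idx[k:]
    if not fit_idx or not test_idx:
        raise ValueError(
            f"fit_fraction {protocol.fit_fraction} leaves an empty side for n={n}"
        )
    return [records[i] for i in sorted(fit_idx)], [records[i] for i in sorted(test_idx)]
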