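"""End-to-end training and recognition orchestration.

Training: sample sub-volumes from every video, fit one global PCA
whitener on the pooled samples, learn a per-class dictionary (RICA or
the k-means baseline) on each class's whitened samples, pool the
dictionaries into a codebook, encode every training video into a
sparse histogram, expand with the chi-square kernel map, and train
one-vs-rest linear SVMs.  Recognition runs the same feature chain and
takes the arg-max of the per-class decision values.

A trained model serializes to a single ``.npz`` archive of named
arrays plus an embedded JSON config; archives round-trip bit-exactly
and loading refuses a mismatched format version.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .classification import (
    ClassifierSet,
    EvaluationReport,
    KernelMapConfig,
    chi2_feature_map,
    evaluate_new_person as _evaluate_new_person,
    train_ovr_svm,
)
from .dictionary_learning import (
    Codebook,
    Whitener,
    fit_whitener,
    kmeans_dictionary,
    learn_dictionary,
    pool_codebook,
)
from .errors import ValidationError
from .skeleton_io import SkeletonSequence
from .sparse_coding import ActivityHistogram, encode_samples, video_histogram
from .volume_sampling import build_volume, sample_subvolumes

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "TrainedModel",
    "train_pipeline",
    "predict",
    "encode_sequence",
    "evaluate_new_person",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one serializable place.

    ``r3`` is the temporal window length in frames (11 suits ~30 Hz
    capture; slower frame rates warrant larger windows).  ``n_words``
    (K) and ``top_l`` (L) default to the full-scale setting of 400
    each; :meth:`small` is a reduced preset for quick experiments and
    tests.
    """

    r3: int = 11
    stride: int = 1
    n_words: int = 400  # words per class dictionary (K)
    top_l: int = 400  # kept coefficients per sample (L)
    lam: float = 0.5  # RICA sparsity/reconstruction balance
    whiten_eps: float = 1e-5
    svm_reg: float = 0.01
    kernel_order: int = 1
    kernel_period: Optional[float] = None  # None -> calibrated default
    dictionary_method: str = "rica"  # or "kmeans"
    normalize_histograms: bool = True
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r3 < 1 or self.stride < 1 or self.n_words < 1 or self.top_l < 1:
            raise ValidationError("r3, stride, n_words and top_l must be positive")
        if self.dictionary_method not in ("rica", "kmeans"):
            raise ValidationError(
                f"unknown dictionary_method '{self.dictionary_method}'"
            )

    @classmethod
    def small(cls, **overrides) -> "PipelineConfig":
        """Reduced-size preset (K = L = 32) for tests and small corpora."""
        defaults = dict(n_words=32, top_l=32)
        defaults.update(overrides)
        return cls(**defaults)

    def kernel_config(self) -> KernelMapConfig:
        if self.kernel_period is None:
            if self.kernel_order == 1:
                return KernelMapConfig()
            return KernelMapConfig.chi2_spectrum(order=self.kernel_order)
        return KernelMapConfig.chi2_spectrum(
            order=self.kernel_order, period=self.kernel_period
        )


@dataclass
class TrainedModel:
    """Everything needed to classify a new sequence."""

    codebook: Codebook
    top_l: int
    kernel_cfg: KernelMapConfig
    classifiers: ClassifierSet
    config: PipelineConfig
    n_joints: int
    format_version: int = FORMAT_VERSION

    @property
    def classes(self) -> list[str]:
        return self.classifiers.classes

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": self.format_version,
            "package_version": _pkg_version,
            "top_l": self.top_l,
            "n_joints": self.n_joints,
            "layout": self.codebook.layout,
            "classes": self.classifiers.classes,
            "class_slices": {k: list(v) for k, v in self.codebook.class_slices.items()},
            "svm_reg": self.classifiers.reg,
            "kernel": {
                "order": self.kernel_cfg.order,
                "period": self.kernel_cfg.period,
                "weights": list(self.kernel_cfg.weights),
            },
            "whiten_eps": self.codebook.whitener.eps,
            "config": asdict(self.config),
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
            codebook_words=self.codebook.words,
            whitener_mean=self.codebook.whitener.mean,
            whitener_transform=self.codebook.whitener.transform,
            svm_weights=self.classifiers.weights,
            svm_biases=self.classifiers.biases,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta"]).decode())
            if meta.get("format_version") != FORMAT_VERSION:
                raise ValidationError(
                    f"model archive format version {meta.get('format_version')} "
                    f"is not supported (expected {FORMAT_VERSION})"
                )
            whitener = Whitener(
                mean=archive["whitener_mean"],
                transform=archive["whitener_transform"],
                eps=float(meta["whiten_eps"]),
            )
            codebook = Codebook(
                words=archive["codebook_words"],
                class_slices={k: tuple(v) for k, v in meta["class_slices"].items()},
                whitener=whitener,
                layout=meta["layout"],
            )
            classifiers = ClassifierSet(
                weights=archive["svm_weights"],
                biases=archive["svm_biases"],
                classes=list(meta["classes"]),
                reg=float(meta["svm_reg"]),
            )
        kernel_cfg = KernelMapConfig(
            order=int(meta["kernel"]["order"]),
            period=float(meta["kernel"]["period"]),
            weights=tuple(meta["kernel"]["weights"]),
        )
        return cls(
            codebook=codebook,
            top_l=int(meta["top_l"]),
            kernel_cfg=kernel_cfg,
            classifiers=classifiers,
            config=PipelineConfig(**meta["config"]),
            n_joints=int(meta["n_joints"]),
        )


def _sequence_samples(seq: SkeletonSequence, config: PipelineConfig):
    return sample_subvolumes(build_volume(seq), config.r3, config.stride)


def encode_sequence(
    codebook: Codebook, seq: SkeletonSequence, config: PipelineConfig
) -> ActivityHistogram:
    """Run one sequence through sampling, projection, top-L keeping and
    histogram pooling."""
    samples = _sequence_samples(seq, config)
    codes = encode_samples(codebook, samples.columns, config.top_l)
    return video_histogram(
        codes, codebook.n_words, normalize=config.normalize_histograms
    )


def train_pipeline(
    sequences: Sequence[SkeletonSequence], config: Optional[PipelineConfig] = None
) -> TrainedModel:
    """Train the full recognition model on labeled sequences."""
    if config is None:
        config = PipelineConfig()
    if not sequences:
        raise ValidationError("no training sequences")
    joints = {s.n_joints for s in sequences}
    if len(joints) != 1:
        raise ValidationError(f"sequences disagree on joint count: {sorted(joints)}")
    classes = sorted({s.activity_label for s in sequences})
    if len(classes) < 2:
        raise ValidationError("need at least 2 activity classes")
    short = [s.n_frames for s in sequences if s.n_frames < config.r3]
    if short:
        raise ValidationError(
            f"{len(short)} sequence(s) shorter than r3={config.r3} frames"
        )

    t0 = time.perf_counter()
    per_video = [_sequence_samples(s, config) for s in sequences]
    pooled = np.concatenate([m.columns for m in per_video], axis=1)
    logger.info(
        "sampling: %d videos -> %d samples of dim %d (%.2fs)",
        len(sequences), pooled.shape[1], pooled.shape[0], time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    whitener = fit_whitener(pooled, eps=config.whiten_eps)
    logger.info("whitening fitted (%.2fs)", time.perf_counter() - t0)

    dicts = []
    for cls in classes:
        cls_samples = np.concatenate(
            [m.columns for m in per_video if m.activity_label == cls], axis=1
        )
        t0 = time.perf_counter()
        white = whitener.apply(cls_samples)
        if config.dictionary_method == "rica":
            d = learn_dictionary(
                white,
                config.n_words,
                config.lam,
                seed=config.seed,
                max_iter=config.max_iter,
                activity_label=cls,
            )
        else:
            d = kmeans_dictionary(
                white, config.n_words, seed=config.seed, activity_label=cls
            )
        logger.info(
            "dictionary '%s': %d words from %d samples (%.2fs)",
            cls, config.n_words, white.shape[1], time.perf_counter() - t0,
        )
        dicts.append(d)
    codebook = pool_codebook(dicts, whitener)

    t0 = time.perf_counter()
    kernel_cfg = config.kernel_config()
    feats = []
    for m in per_video:
        codes = encode_samples(codebook, m.columns, config.top_l)
        hist = video_histogram(
            codes, codebook.n_words, normalize=config.normalize_histograms
        )
        feats.append(chi2_feature_map(hist, kernel_cfg))
    features = np.vstack(feats)
    logger.info(
        "encoding: %d histograms of %d bins -> features of dim %d (%.2fs)",
        len(feats), codebook.n_words, features.shape[1], time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    classifiers = train_ovr_svm(
        features,
        [s.activity_label for s in sequences],
        reg=config.svm_reg,
        seed=config.seed,
    )
    logger.info("SVM training done (%.2fs)", time.perf_counter() - t0)
    return TrainedModel(
        codebook=codebook,
        top_l=config.top_l,
        kernel_cfg=kernel_cfg,
        classifiers=classifiers,
        config=config,
        n_joints=sequences[0].n_joints,
    )


def predict(
    model: TrainedModel, seq: SkeletonSequence
) -> tuple[str, np.ndarray]:
    """Classify one sequence; returns the label and per-class scores
    (ordered like ``model.classes``; ties break toward earlier classes)."""
    if seq.n_joints != model.n_joints:
        raise ValidationError(
            f"sequence has {seq.n_joints} joints but the model expects "
            f"{model.n_joints}"
        )
    if seq.n_frames < model.config.r3:
        raise ValidationError(
            f"sequence too short: {seq.n_frames} frames < r3={model.config.r3}"
        )
    hist = encode_sequence(model.codebook, seq, model.config)
    feat = chi2_feature_map(hist, model.kernel_cfg)
    scores = model.classifiers.decision_values(feat)
    return model.classes[int(np.argmax(scores))], scores


def evaluate_new_person(
    dataset: Sequence[SkeletonSequence], config: Optional[PipelineConfig] = None
) -> EvaluationReport:
    """Leave-one-subject-out evaluation (delegates to
    :func:`jointcodes.classification.evaluate_new_person`)."""
    return _evaluate_new_person(dataset, config)
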