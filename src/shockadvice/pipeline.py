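"""End-to-end shock-advice pipeline: preprocess -> MVMD -> CNNE -> classifier.

The deployed decision path for one raw 8-s ECG segment is

    raw -> pECG (filter chain) -> {pECG, SH, NSH} channels (MVMD)
        -> 100-d deep feature vector (pre-trained CNNE, first FC)
        -> SH/NSH label (pre-trained conventional classifier, BS by default)

`SaaPipeline` bundles the trained artifacts and runs that path with a
per-stage timing log; `prepare_channel_stacks` is the shared batch front-end
(segmentation, exclusions, filtering, decomposition) used by training,
validation and the CLI.
"""

from __future__ import annotations

import pickle
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from .cnn import CnnModel, extract_features, load_model, save_model
from .mvmd import MvmdParams, build_channels, mvmd_decompose
from .preprocess import apply_exclusions, preprocess_segment, segment_record
from .records import ChannelStack, EcgRecord, Segment

__all__ = ["SaaPipeline", "prepare_channel_stacks", "train_pipeline"]

FLATLINE_PP_MV = 0.05  # below this peak-to-peak, advise with a warning


def prepare_channel_stacks(
    records: list[EcgRecord],
    seg_len_s: float = 8.0,
    mvmd_params: MvmdParams | None = None,
    exclusions: bool = True,
) -> list[ChannelStack]:
    """Batch front-end: records -> labeled 3-channel stacks.

    Segments each record, applies the exclusion rules, filters each retained
    segment and decomposes it into the SH/NSH channels.
    """
    stacks = []
    for rec in records:
        segments = segment_record(rec, seg_len_s)
        if exclusions:
            segments = apply_exclusions(segments, rec.fs)
        for seg in segments:
            pecg = preprocess_segment(seg.samples, rec.fs)
            modes = mvmd_decompose(pecg, rec.fs, mvmd_params)
            stacks.append(
                build_channels(pecg, modes, label=seg.label, record_id=rec.record_id)
            )
    return stacks


@dataclass
class SaaPipeline:
    """Pre-trained artifacts plus the settings they were trained under."""

    extractor: CnnModel
    classifier: object
    classifier_spec: _classify.ClassifierSpec
    fs: float = 250.0
    seg_len_s: float = 8.0
    mvmd_params: MvmdParams = field(default_factory=MvmdParams)

    def run_saa(self, samples: np.ndarray, fs: float | None = None):
        """Classify one raw segment; returns (label, info).

        ``info`` carries the channel stack, the feature vector, and per-stage
        wall-clock timings.  A near-flat input still yields a label but with
        a low-confidence warning.
        """
        fs = self.fs if fs is None else fs
        x = np.asarray(samples, dtype=float)
        expected = int(round(fs * self.seg_len_s))
        if len(x) != expected:
            raise ValueError(
                f"expected a {self.seg_len_s} s segment ({expected} samples at "
                f"{fs} Hz), got {len(x)} samples"
            )
        timings = {}
        if np.ptp(x) < FLATLINE_PP_MV:
            warnings.warn(
                "near-flat input (peak-to-peak < 50 uV): label is low-confidence",
                stacklevel=2,
            )
        t0 = time.perf_counter()
        pecg = preprocess_segment(x, fs)
        timings["preprocess"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        modes = mvmd_decompose(pecg, fs, self.mvmd_params)
        stack = build_channels(pecg, modes)
        timings["mvmd"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        feats = extract_features(self.extractor, stack)
        timings["features"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        label = int(_classify.predict(self.classifier, feats)[0])
        timings["classify"] = time.perf_counter() - t0

        return label, {"stack": stack, "features": feats, "timings": timings}

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_model(self.extractor, d / "extractor.npz")
        with open(d / "classifier.pkl", "wb") as fh:
            pickle.dump(
                {"classifier": self.classifier, "spec": self.classifier_spec,
                 "fs": self.fs, "seg_len_s": self.seg_len_s,
                 "mvmd_params": self.mvmd_params}, fh,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "SaaPipeline":
        d = Path(directory)
        extractor = load_model(d / "extractor.npz")
        with open(d / "classifier.pkl", "rb") as fh:
            blob = pickle.load(fh)
        return cls(extractor=extractor, classifier=blob["classifier"],
                   classifier_spec=blob["spec"], fs=blob["fs"],
                   seg_len_s=blob["seg_len_s"], mvmd_params=blob["mvmd_params"])


def train_pipeline(
    train_stacks: list[ChannelStack],
    config=None,
    classifier_spec: _classify.ClassifierSpec | None = None,
    fs: float = 250.0,
    seg_len_s: float = 8.0,
    mvmd_params: MvmdParams | None = None,
    epochs: int | None = None,
    seed: int = 0,
) -> SaaPipeline:
    """Train extractor + secondary classifier on prepared channel stacks."""
    from .cnn import CnnConfig, build_cnne, train_cnne

    if config is None:
        config = CnnConfig()          # the selected shock-advice network
    if classifier_spec is None:
        classifier_spec = _classify.ClassifierSpec(name="BS", seed=seed)
    extractor = build_cnne(config, seed=seed)
    train_cnne(extractor, train_stacks, epochs=epochs, seed=seed)
    feats = extract_features(extractor, train_stacks)
    labels = np.array([s.label for s in train_stacks], dtype=int)
    clf = _classify.train_classifier(classifier_spec, feats, labels)
    return SaaPipeline(extractor=extractor, classifier=clf,
                       classifier_spec=classifier_spec, fs=fs,
                       seg_len_s=seg_len_s,
                       mvmd_params=mvmd_params or MvmdParams())
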