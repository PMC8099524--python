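"""Model/Results interface over the cycle-consistent synthesis machinery.

:class:`RoiCycleGan` is built from paired (image, mask) samples plus a
:class:`~roigan.training.TrainConfig`; ``fit()`` runs the alternating
optimization and returns a :class:`RoiCycleGanResults` carrying the trained
parameters, the per-step loss history, a ``summary()`` table, and the two
synthesis pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthesis
from .phantoms import PairedSample
from .training import TrainConfig, TrainState, train


class RoiCycleGan:
    """Paired image/ROI synthesis model with regional feature fusion.

    Parameters
    ----------
    samples : list of PairedSample
        Training pairs; images in [0,1], masks binary, all of size
        ``config.image_size``.
    config : TrainConfig, optional
        Defaults to the full-scale recipe; use ``TrainConfig.desk_scale()``
        for short CPU runs.
    """

    def __init__(self, samples: list[PairedSample],
                 config: TrainConfig | None = None):
        if not samples:
            raise ValueError("need at least one training sample")
        self.config = config or TrainConfig()
        s = self.config.image_size
        for smp in samples:
            if smp.image.shape != (s, s):
                raise ValueError(
                    f"sample {smp.sample_id!r} has shape {smp.image.shape}, "
                    f"config.image_size is {s}")
        self.samples = list(samples)

    @classmethod
    def from_manifest(cls, manifest_path, config: TrainConfig | None = None):
        from .preprocess import read_manifest

        return cls(read_manifest(manifest_path), config)

    def fit(self, callback=None) -> "RoiCycleGanResults":
        state = train(self.samples, self.config, callback=callback)
        return RoiCycleGanResults(self, state)


class RoiCycleGanResults:
    """Fitted model: trained parameters, loss history, synthesis."""

    def __init__(self, model: RoiCycleGan | None, state: TrainState):
        self.model = model
        self.state = state

    # -- diagnostics ---------------------------------------------------------

    @property
    def loss_history(self) -> pd.DataFrame:
        return self.state.history_frame()

    def summary(self) -> str:
        h = self.loss_history
        cfg = self.state.config
        lines = [
            "Cycle-consistent paired synthesis (regional feature fusion)",
            "=" * 60,
            f"optimizer steps: {self.state.step}   epochs: {self.state.epoch}",
            f"image size: {cfg.image_size}   cycle weight: {cfg.cycle_weight}",
            f"learning rate: {cfg.learning_rate}   seed: {cfg.seed}",
        ]
        if len(h):
            k = min(20, len(h))
            lines += [
                "-" * 60,
                f"{'term':<12}{'first-%d mean' % k:>16}{'last-%d mean' % k:>16}",
            ]
            for term in ("L_GAN_fwd", "L_GAN_bwd", "L_cyc", "total"):
                lines.append(f"{term:<12}{h[term].head(k).mean():>16.4f}"
                             f"{h[term].tail(k).mean():>16.4f}")
        return "\n".join(lines)

    # -- synthesis -----------------------------------------------------------

    def synthesize_image(self, sample: PairedSample) -> synthesis.SynthesisResult:
        return synthesis.synthesize_image(sample, self.state)

    def synthesize_roi(self, sample: PairedSample,
                       threshold: float = 0.5) -> synthesis.SynthesisResult:
        return synthesis.synthesize_roi(sample, self.state, threshold)

    def synthesize_pair(self, sample: PairedSample,
                        threshold: float = 0.5) -> synthesis.SynthesisResult:
        return synthesis.synthesize_pair(sample, self.state, threshold)

    def synthesize_batch(self, samples, out_dir, threshold: float = 0.5):
        return synthesis.synthesize_batch(samples, self.state, out_dir,
                                          threshold)

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        self.state.save(path)

    @classmethod
    def load(cls, path) -> "RoiCycleGanResults":
        return cls(None, TrainState.load(path))
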