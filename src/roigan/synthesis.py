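"""Inference: paired synthesis of medical images and ROI masks from a
trained model.

Both pipelines start from a real (image, mask) seed pair, because the
domain-X input is the image fused with RFB features of its region image —
there is no noise input to sample from.  (i) image synthesis:
x -> G(x) -> F(G(x)); (ii) ROI synthesis: y -> F(y) -> G(F(y)), where G's
input is rebuilt from F(y) and the seed mask, and the soft output is
binarized at a threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import networks, nn
from .phantoms import PairedSample
from .training import TrainState


@dataclass
class SynthesisResult:
    source: PairedSample
    g_of_x: np.ndarray | None = None
    synthetic_image: np.ndarray | None = None
    f_of_y: np.ndarray | None = None
    synthetic_roi_soft: np.ndarray | None = None
    synthetic_roi: np.ndarray | None = None


def _nets(state: TrainState):
    for name, p in state.params.items():
        for k, v in p.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(
                    f"untrained or corrupt state: non-finite parameters in "
                    f"{name}/{k}")
    return state.networks()


def _fused(state, nets, img, msk):
    region = img * msk
    feats, _ = nets["rfb"].forward(state.params["rfb"], region)
    return networks.fuse_regional_features(img, feats)


def synthesize_image(sample: PairedSample, state: TrainState,
                     result: SynthesisResult | None = None) -> SynthesisResult:
    """Medical-image pipeline: returns G(x) and the synthetic image
    F(G(x)), both with the source's spatial dims, deterministically."""
    nets = _nets(state)
    img = sample.image.astype(nn.DTYPE)[None]
    msk = sample.mask.astype(nn.DTYPE)[None]
    fused = _fused(state, nets, img, msk)
    gx, _ = nets["g"].forward(state.params["g"], fused)
    fgx, _ = nets["f"].forward(state.params["f"], gx)
    out = result or SynthesisResult(source=sample)
    out.g_of_x = gx[0]
    out.synthetic_image = np.clip(fgx[0], 0.0, 1.0)
    return out


def synthesize_roi(sample: PairedSample, state: TrainState,
                   threshold: float = 0.5,
                   result: SynthesisResult | None = None) -> SynthesisResult:
    """ROI pipeline: returns F(y), the soft map G(F(y)) in [0,1], and the
    thresholded binary mask."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    nets = _nets(state)
    msk = sample.mask.astype(nn.DTYPE)[None]
    fy, _ = nets["f"].forward(state.params["f"], msk)
    fused = _fused(state, nets, fy, msk)
    gfy, _ = nets["g"].forward(state.params["g"], fused)
    out = result or SynthesisResult(source=sample)
    out.f_of_y = fy[0]
    out.synthetic_roi_soft = gfy[0]
    out.synthetic_roi = (gfy[0] >= threshold).astype(np.uint8)
    return out


def synthesize_pair(sample: PairedSample, state: TrainState,
                    threshold: float = 0.5) -> SynthesisResult:
    """Both pipelines from the same seed pair (the paired-output contract:
    image and ROI always come from the same cycle)."""
    res = synthesize_image(sample, state)
    return synthesize_roi(sample, state, threshold, result=res)


def synthesize_batch(samples, state: TrainState, out_dir,
                     threshold: float = 0.5):
    """Synthesize paired image/ROI for each sample and write them as PNG
    pairs plus a manifest tagged synthetic; group labels are preserved for
    downstream classification. Returns the manifest DataFrame."""
    from .preprocess import write_pairs

    out_samples = []
    for s in samples:
        r = synthesize_pair(s, state, threshold)
        out_samples.append(PairedSample(
            image=r.synthetic_image, mask=r.synthetic_roi,
            sample_id=f"synthetic_{s.sample_id}", group_label=s.group_label))
    manifest = write_pairs(out_samples, out_dir)
    manifest["provenance"] = "synthetic"
    import pandas as pd  # manifest.csv rewritten with the provenance column
    from pathlib import Path

    manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest
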