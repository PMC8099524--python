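"""Alternating optimization of the two-generator / two-discriminator cycle
model with regional feature fusion.

Per optimizer step (batch size 1): the domain-X input is the medical image
channel-fused with RFB features of its region image (image x mask); the
domain-Y input is the ROI mask.  The discriminators D_x and D_y are updated
first to maximize the adversarial objective, then G, F and the RFB are
updated jointly to minimize the combined objective (adversarial terms as
written — the saturating form — plus the weighted cycle term; a flag enables
the standard non-saturating -log D(G(x)) variant).  The RFB receives
gradients through both cycle directions.  Runs are deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import losses, networks, nn
from .phantoms import PairedSample
from .preprocess import compute_region_image

_CLAMP = losses.LOG_CLAMP


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the published full-scale recipe: Adam with default betas
    (0.9, 0.999), learning rate 2e-4, 300 epochs, batch size 1.  ``max_steps``
    caps the total optimizer steps regardless of epochs (desk-scale runs).
    """

    epochs: int = 300
    learning_rate: float = 2e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 1
    cycle_weight: float = 10.0
    seed: int = 0
    image_size: int = 64
    feature_channels: int = 8
    max_steps: int | None = None
    non_saturating: bool = False
    device: str = "cpu"

    def validate(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.cycle_weight < 0:
            raise ValueError("cycle_weight must be >= 0")
        if self.batch_size != 1:
            raise ValueError("only batch_size=1 is supported "
                             "(instance-norm, per-sample statistics)")

    @classmethod
    def desk_scale(cls, seed: int = 0, image_size: int = 64,
                   max_steps: int = 300) -> "TrainConfig":
        """Short CPU profile: ~150x fewer optimizer steps than a full run,
        compensated by a larger learning rate and beta1=0.5 (standard GAN
        practice for short adversarial schedules)."""
        return cls(epochs=10 ** 9, learning_rate=2e-3, adam_beta1=0.5,
                   seed=seed, image_size=image_size, max_steps=max_steps)


@dataclass
class TrainState:
    """Trained model: network specs, parameters, optimizer state, loss
    history."""

    specs: dict
    params: dict
    optimizers: dict
    config: TrainConfig
    step: int = 0
    epoch: int = 0
    history: list = field(default_factory=list)

    def networks(self) -> dict:
        return {name: networks.Network(spec) for name, spec in self.specs.items()}

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    # -- checkpointing ------------------------------------------------------

    def save(self, path):
        arrays = {}
        for net, p in self.params.items():
            for k, v in p.items():
                arrays[f"param/{net}/{k}"] = v
        for net, opt in self.optimizers.items():
            st = opt.state()
            for k, v in st["m"].items():
                arrays[f"adam_m/{net}/{k}"] = v
            for k, v in st["v"].items():
                arrays[f"adam_v/{net}/{k}"] = v
            arrays[f"adam_t/{net}"] = np.array(st["t"])
        meta = {
            "config": asdict(self.config),
            "specs": {k: json.loads(v.to_json()) for k, v in self.specs.items()},
            "step": self.step,
            "epoch": self.epoch,
            "history": self.history,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TrainState":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
        config = TrainConfig(**meta["config"])
        specs = {k: networks.NetworkSpec.from_json(json.dumps(v))
                 for k, v in meta["specs"].items()}
        params: dict = {k: {} for k in specs}
        adam_m: dict = {k: {} for k in specs}
        adam_v: dict = {k: {} for k in specs}
        adam_t: dict = {}
        for key in data.files:
            if key == "meta":
                continue
            kind, net, *rest = key.split("/")
            if kind == "param":
                params[net][rest[0]] = data[key]
            elif kind == "adam_m":
                adam_m[net][rest[0]] = data[key]
            elif kind == "adam_v":
                adam_v[net][rest[0]] = data[key]
            elif kind == "adam_t":
                adam_t[net] = int(data[key])
        optimizers = {}
        for net in specs:
            opt = nn.Adam(params[net], lr=config.learning_rate,
                          beta1=config.adam_beta1, beta2=config.adam_beta2)
            opt.m = adam_m[net]
            opt.v = adam_v[net]
            opt.t = adam_t[net]
            optimizers[net] = opt
        return cls(specs=specs, params=params, optimizers=optimizers,
                   config=config, step=meta["step"], epoch=meta["epoch"],
                   history=meta["history"])


# ---------------------------------------------------------------------------


def init_state(config: TrainConfig) -> TrainState:
    """Build specs and Gaussian(0, 0.02)-initialized parameters, seeded."""
    config.validate()
    s = config.image_size
    fc = config.feature_channels
    specs = {
        "rfb": networks.build_rfb_spec(s, fc),
        "g": networks.build_generator_spec(s, 1 + fc, name="generator_G"),
        "f": networks.build_generator_spec(s, 1, name="generator_F"),
        "dx": networks.build_discriminator_spec(s, 1, name="discriminator_Dx"),
        "dy": networks.build_discriminator_spec(s, 1, name="discriminator_Dy"),
    }
    rng = np.random.default_rng(config.seed)
    params = {}
    optimizers = {}
    for name in ("rfb", "g", "f", "dx", "dy"):  # fixed order for determinism
        net = networks.Network(specs[name])
        params[name] = net.init_params(rng)
        optimizers[name] = nn.Adam(params[name], lr=config.learning_rate,
                                   beta1=config.adam_beta1,
                                   beta2=config.adam_beta2)
    return TrainState(specs=specs, params=params, optimizers=optimizers,
                      config=config)


def _check_finite(value: float, step: int, term: str):
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite loss at step {step}: term {term!r} = {value}")


def _accumulate(into: dict, grads: dict):
    for k, v in grads.items():
        into[k] += v


def _disc_update(net: networks.Network, params, opt, real, fake):
    """One discriminator ascent step on log D(real) + log(1 - D(fake)).
    Returns the adversarial-loss value (pre-update outputs)."""
    dr, tape_r = net.forward(params, real)
    drc = np.clip(dr, _CLAMP, 1 - _CLAMP)
    # maximize => minimize negative; d(-log dr)/d dr = -1/dr
    _, grads_r = net.backward(params, tape_r, (-1.0 / drc).astype(real.dtype))
    df, tape_f = net.forward(params, fake)
    dfc = np.clip(df, _CLAMP, 1 - _CLAMP)
    _, grads_f = net.backward(params, tape_f, (1.0 / (1.0 - dfc)).astype(real.dtype))
    _accumulate(grads_r, grads_f)
    opt.step(params, grads_r)
    return float(np.log(drc).sum() + np.log(1.0 - dfc).sum())


def _adv_input_grad(net: networks.Network, params, fake, non_saturating):
    """Gradient of the generator's adversarial term w.r.t. the fake input,
    backpropagated through a frozen discriminator. Returns (grad, d_fake)."""
    df, tape = net.forward(params, fake)
    dfc = np.clip(df, _CLAMP, 1 - _CLAMP)
    if non_saturating:
        gout = (-1.0 / dfc).astype(fake.dtype)       # minimize -log D(fake)
    else:
        gout = (-1.0 / (1.0 - dfc)).astype(fake.dtype)  # minimize log(1-D(fake))
    gx, _ = net.backward(params, tape, gout)
    return gx, float(dfc.sum())


def train(samples: list[PairedSample], config: TrainConfig,
          state: TrainState | None = None,
          callback=None) -> TrainState:
    """Run the alternating optimization loop and return the TrainState with
    a complete per-step loss history.

    Update order per step: D_x, D_y ascent on the adversarial objective with
    detached fakes, then one joint descent step for G, F and the RFB on
    adv_xy + adv_yx + cycle_weight * L_cyc.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    config.validate()
    if state is None:
        state = init_state(config)
    nets = state.networks()
    rfb, g, f = nets["rfb"], nets["g"], nets["f"]
    dx, dy = nets["dx"], nets["dy"]
    p = state.params
    lam = config.cycle_weight
    rng = np.random.default_rng(config.seed + 1)  # data order stream
    npix = config.image_size ** 2

    imgs = [s.image.astype(nn.DTYPE)[None] for s in samples]
    msks = [s.mask.astype(nn.DTYPE)[None] for s in samples]

    def fused_input(img, msk):
        region = (img * msk)
        feats, rtape = rfb.forward(p["rfb"], region)
        return networks.fuse_regional_features(img, feats), rtape

    done = False
    for epoch in range(config.epochs):
        if done:
            break
        for i in rng.permutation(len(samples)):
            if config.max_steps is not None and state.step >= config.max_steps:
                done = True
                break
            img, msk = imgs[i], msks[i]

            # ---- discriminator updates (fakes detached) -------------------
            fused, _ = fused_input(img, msk)
            gx_det, _ = g.forward(p["g"], fused)
            fy_det, _ = f.forward(p["f"], msk)
            adv_xy = _disc_update(dy, p["dy"], state.optimizers["dy"],
                                  real=msk, fake=gx_det)
            adv_yx = _disc_update(dx, p["dx"], state.optimizers["dx"],
                                  real=img, fake=fy_det)

            # ---- joint generator / RFB update -----------------------------
            grads = {name: {k: np.zeros_like(v) for k, v in p[name].items()}
                     for name in ("g", "f", "rfb")}

            # direction X: x -> G(x) -> F(G(x)) ~ image
            fused, rtape = fused_input(img, msk)
            gx, gtape = g.forward(p["g"], fused)
            fgx, ftape = f.forward(p["f"], gx)
            cyc_x = float(np.mean(np.abs(fgx - img)))
            d_fgx = (lam * np.sign(fgx - img) / npix).astype(nn.DTYPE)
            g_gx_cyc, gr_f = f.backward(p["f"], ftape, d_fgx)
            _accumulate(grads["f"], gr_f)
            g_gx_adv, _ = _adv_input_grad(dy, p["dy"], gx, config.non_saturating)
            g_fused, gr_g = g.backward(p["g"], gtape, g_gx_cyc + g_gx_adv)
            _accumulate(grads["g"], gr_g)
            _, gr_rfb = rfb.backward(p["rfb"], rtape, g_fused[1:])
            _accumulate(grads["rfb"], gr_rfb)

            # direction Y: y -> F(y) -> G(fuse(F(y), RFB(F(y)*y))) ~ mask
            fy, ftape2 = f.forward(p["f"], msk)
            region2 = fy * msk
            feats2, rtape2 = rfb.forward(p["rfb"], region2)
            fused2 = networks.fuse_regional_features(fy, feats2)
            gfy, gtape2 = g.forward(p["g"], fused2)
            cyc_y = float(np.mean(np.abs(gfy - msk)))
            d_gfy = (lam * np.sign(gfy - msk) / npix).astype(nn.DTYPE)
            g_fused2, gr_g2 = g.backward(p["g"], gtape2, d_gfy)
            _accumulate(grads["g"], gr_g2)
            g_region2, gr_rfb2 = rfb.backward(p["rfb"], rtape2, g_fused2[1:])
            _accumulate(grads["rfb"], gr_rfb2)
            g_fy = g_fused2[:1] + g_region2 * msk
            g_fy_adv, _ = _adv_input_grad(dx, p["dx"], fy, config.non_saturating)
            _, gr_f2 = f.backward(p["f"], ftape2, g_fy + g_fy_adv)
            _accumulate(grads["f"], gr_f2)

            for name in ("g", "f", "rfb"):
                state.optimizers[name].step(p[name], grads[name])

            cyc = cyc_x + cyc_y
            total = losses.total_objective(adv_xy, adv_yx, cyc, lam)
            for term, val in (("L_GAN_fwd", adv_xy), ("L_GAN_bwd", adv_yx),
                              ("L_cyc", cyc), ("total", total)):
                _check_finite(val, state.step, term)
            state.history.append({
                "step": state.step, "epoch": epoch,
                "L_GAN_fwd": adv_xy, "L_GAN_bwd": adv_yx,
                "L_cyc": cyc, "L_cyc_x": cyc_x, "L_cyc_y": cyc_y,
                "total": total,
            })
            state.step += 1
            if callback is not None:
                callback(state)
        state.epoch = epoch + 1
    return state
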