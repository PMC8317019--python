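"""The learned proximal gradient method: prox-nets, unrolling, and training.

The reconstruction operator unrolls a fixed number of proximal gradient
iterations and replaces each proximal step by a small learnable network,
carrying a memory state ``s`` between iterations:

    u <- u0 (zero), s <- 0
    for i in 1..it:  (u, s) <- proxnet_i(u, s, grad E_y(u))
    return u

Each prox-net is three affine convolution layers with a single residual
nonlinearity,

    proxnet_i = K_project,i o (id + phi o K_intermediate,i) o K_lift,i,

where phi is a leaky ReLU (slope 0.01).  Two flavours are provided with
identical activation shapes ("width-matched"): the ordinary flavour uses
unconstrained convolutions; the equivariant flavour parameterises every
kernel in the steerable basis of Z_m, lifting trivial input fields (the
image, memory and gradient channels) to regular-representation fields and
projecting back, so each prox-net commutes with the roto-translations of
Z_m.  The ordinary parameterisation is a superset: any equivariant net can
be embedded into an ordinary one reproducing its outputs exactly.

Training minimises the empirical risk (1/N) sum_i ||u_i - Phi(y_i)||^2 with
Adam at minibatch size 1.  Everything is NumPy: gradients are computed by
hand-written reverse-mode passes through the convolutions, the basis
expansion and the data-discrepancy gradient steps (whose Jacobian is the
self-adjoint normal operator A^T A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .equivariant_ops import (
    EquivariantConvLayer,
    bias_field_grad,
    conv2d,
    conv2d_backward,
    expand_kernel,
    kernel_coefficient_grad,
    leaky_relu,
    leaky_relu_grad,
)
from .forward_models import LinearOperatorPair
from .groups import CyclicGroup, regular_representation, trivial_representation


# ---------------------------------------------------------------------------
# Affine convolution layers (a common interface for both flavours)
# ---------------------------------------------------------------------------


@dataclass
class OrdinaryConvLayer:
    """Unconstrained convolution + per-channel bias."""

    kernel: np.ndarray  # [C_out, C_in, s, s]
    bias: np.ndarray  # [C_out]
    padding: str = "zeros"

    def forward(self, x: np.ndarray) -> np.ndarray:
        return conv2d(x, self.kernel, self.padding) + self.bias[:, None, None]

    def backward(self, x: np.ndarray, dy: np.ndarray):
        dx, dk = conv2d_backward(x, self.kernel, dy, self.padding)
        return dx, {"kernel": dk, "bias": dy.sum(axis=(-2, -1))}

    def params(self) -> dict:
        return {"kernel": self.kernel, "bias": self.bias}

    def set_params(self, p: dict) -> None:
        self.kernel = p["kernel"]
        self.bias = p["bias"]


@dataclass
class SteerableLayerAdapter:
    """Training adapter around EquivariantConvLayer: forward through the basis
    expansion and back-propagation onto the basis coefficients and tied biases."""

    layer: EquivariantConvLayer

    def forward(self, x: np.ndarray) -> np.ndarray:
        kernel = expand_kernel(self.layer)
        return conv2d(x, kernel, self.layer.padding) + self.layer.bias_vector()[
            :, None, None
        ]

    def backward(self, x: np.ndarray, dy: np.ndarray):
        kernel = expand_kernel(self.layer)
        dx, dk = conv2d_backward(x, kernel, dy, self.layer.padding)
        dcoeff = kernel_coefficient_grad(self.layer, dk)
        dbias = bias_field_grad(self.layer, dy)
        grads = {f"c{io}_{ii}": g for (io, ii), g in dcoeff.items()}
        grads["bias"] = dbias
        return dx, grads

    def params(self) -> dict:
        p = {f"c{io}_{ii}": c for (io, ii), c in self.layer.coefficients.items()}
        p["bias"] = self.layer.bias
        return p

    def set_params(self, p: dict) -> None:
        for key in self.layer.coefficients:
            self.layer.coefficients[key] = p[f"c{key[0]}_{key[1]}"]
        self.layer.bias = p["bias"]


# ---------------------------------------------------------------------------
# Prox-nets
# ---------------------------------------------------------------------------


@dataclass
class ProxNet:
    """K_project o (id + phi o K_intermediate) o K_lift with leaky-ReLU phi."""

    lift: OrdinaryConvLayer | SteerableLayerAdapter
    intermediate: OrdinaryConvLayer | SteerableLayerAdapter
    project: OrdinaryConvLayer | SteerableLayerAdapter
    n_image_channels: int
    slope: float = 0.01

    def layers(self):
        return {"lift": self.lift, "intermediate": self.intermediate, "project": self.project}


def prox_net_apply(net: ProxNet, u: np.ndarray, s: np.ndarray, g: np.ndarray):
    """One learned proximal step: concatenate (u, s, g), apply the three-layer
    block, split the output into (u', s')."""
    x = np.concatenate([u, s, g], axis=0)
    h1 = net.lift.forward(x)
    z = net.intermediate.forward(h1)
    h2 = h1 + leaky_relu(z, net.slope)
    out = net.project.forward(h2)
    nu = net.n_image_channels
    cache = (x, h1, z, h2)
    return out[:nu], out[nu:], cache


def prox_net_backward(net: ProxNet, cache, du: np.ndarray, ds: np.ndarray):
    """Reverse-mode pass; returns (du_in, ds_in, dg_in, grads per layer)."""
    x, h1, z, h2 = cache
    dout = np.concatenate([du, ds], axis=0)
    dh2, gproj = net.project.backward(h2, dout)
    dz = dh2 * leaky_relu_grad(z, net.slope)
    dh1_from_int, gint = net.intermediate.backward(h1, dz)
    dh1 = dh2 + dh1_from_int
    dx, glift = net.lift.backward(x, dh1)
    nu = net.n_image_channels
    n_s = ds.shape[0]
    return (
        dx[:nu],
        dx[nu : nu + n_s],
        dx[nu + n_s :],
        {"lift": glift, "intermediate": gint, "project": gproj},
    )


# ---------------------------------------------------------------------------
# The unrolled network
# ---------------------------------------------------------------------------


@dataclass
class NetConfig:
    """Architecture and training constants.

    ``width_product`` is the total number of ordinary channels in the
    intermediate fields (|H| * n_fields for the equivariant flavour); the
    reference-scale value is 96, the desk-scale default 32.  ``it`` is the
    number of unrolled iterations (8), ``memory_channels`` the width of the
    scalar memory state (5), kernels are 3x3.
    """

    modality: Literal["ct", "mri"] = "ct"
    group_order: int = 4
    width_product: int = 32
    it: int = 8
    memory_channels: int = 5
    kernel_size: int = 3
    padding: str = "zeros"
    slope: float = 0.01
    # fixed scalar preconditioner applied to grad E_y before it enters the
    # prox-nets; None means 1/||A||^2 (computed once at build time).  A fixed
    # scalar is absorbable into K_lift, so it changes the parameterisation's
    # conditioning, not the model family (and commutes with rotations).
    grad_scale: float | None = None

    @property
    def n_image_channels(self) -> int:
        return 2 if self.modality == "mri" else 1


@dataclass
class UnrolledNet:
    prox_nets: list
    operator: LinearOperatorPair
    config: NetConfig
    flavour: Literal["ordinary", "equivariant"] = "ordinary"
    grad_scale: float = 1.0

    @property
    def it(self) -> int:
        return len(self.prox_nets)


def build_net(
    flavour: Literal["ordinary", "equivariant"],
    config: NetConfig,
    operator: LinearOperatorPair,
    seed: int = 0,
) -> UnrolledNet:
    """Width-matched ordinary or equivariant unrolled net, initialised per the
    training recipe: He init for lift/project, K_intermediate zero (including
    its bias, so the residual branch is exactly the identity at init)."""
    rng = np.random.default_rng(seed)
    nu = config.n_image_channels
    n_in = 2 * nu + config.memory_channels
    n_out = nu + config.memory_channels
    width = config.width_product
    s = config.kernel_size
    nets = []
    if flavour == "equivariant":
        m = config.group_order
        if width % m != 0:
            raise ValueError(
                f"group order {m} must divide width_product {width}"
            )
        group = CyclicGroup(m)
        triv = trivial_representation(group)
        reg = regular_representation(group)
        n_fields = width // m
        for _ in range(config.it):
            lift = EquivariantConvLayer(
                in_types=[triv] * n_in, out_types=[reg] * n_fields, size=s,
                padding=config.padding,
            )
            lift.he_init(rng)
            inter = EquivariantConvLayer(
                in_types=[reg] * n_fields, out_types=[reg] * n_fields, size=s,
                padding=config.padding,
            )
            inter.zero_init()
            proj = EquivariantConvLayer(
                in_types=[reg] * n_fields, out_types=[triv] * n_out, size=s,
                padding=config.padding,
            )
            proj.he_init(rng)
            nets.append(
                ProxNet(
                    lift=SteerableLayerAdapter(lift),
                    intermediate=SteerableLayerAdapter(inter),
                    project=SteerableLayerAdapter(proj),
                    n_image_channels=nu,
                    slope=config.slope,
                )
            )
    elif flavour == "ordinary":
        # variance-preserving (gain-1) fan-in init: at the zero-intermediate
        # initialisation each prox-net is linear, and a gain above 1 would
        # amplify geometrically across the unrolled iterations
        def he(co, ci):
            return rng.normal(0.0, np.sqrt(1.0 / (ci * s * s)), size=(co, ci, s, s))

        for _ in range(config.it):
            nets.append(
                ProxNet(
                    lift=OrdinaryConvLayer(he(width, n_in), np.zeros(width), config.padding),
                    intermediate=OrdinaryConvLayer(
                        np.zeros((width, width, s, s)), np.zeros(width), config.padding
                    ),
                    project=OrdinaryConvLayer(he(n_out, width), np.zeros(n_out), config.padding),
                    n_image_channels=nu,
                    slope=config.slope,
                )
            )
    else:
        raise ValueError(f"unknown flavour {flavour!r}")
    # calibrate the composed gain of each prox-net (project o lift at the
    # zero-intermediate init) to 1/2 on a white-noise probe.  Steerable
    # kernels are correlated across the channels of a field, so per-layer
    # fan-in scaling alone misestimates the composed gain; and a mild
    # contraction keeps the 8-fold unrolled iteration bounded at init, where
    # each prox-net is still a linear map.  Applied to both flavours so the
    # width-matched comparison starts from the same footing.
    probe = rng.normal(size=(2 * nu + config.memory_channels, 24, 24))
    for pnet in nets:
        h = pnet.lift.forward(probe)
        out = pnet.project.forward(h)
        ratio = float(out.std() / probe.std())
        if ratio > 0:
            pp = pnet.project.params()
            for key in pp:
                if key != "bias":
                    pp[key] = pp[key] * (0.5 / ratio)
            pnet.project.set_params(pp)
    if config.grad_scale is None:
        from .forward_models import operator_norm

        gscale = 1.0 / operator_norm(operator, seed=12345) ** 2
    else:
        gscale = float(config.grad_scale)
    return UnrolledNet(
        prox_nets=nets,
        operator=operator,
        config=config,
        flavour=flavour,
        grad_scale=gscale,
    )


def _as_channels(a: np.ndarray, nu: int) -> np.ndarray:
    return a[None] if (nu == 1 and a.ndim == 2) else a


def _from_channels(a: np.ndarray, op_shape: tuple) -> np.ndarray:
    return a[0] if len(op_shape) == 2 else a


def unrolled_reconstruct(
    net: UnrolledNet, y: np.ndarray, return_cache: bool = False
):
    """Run the unrolled iteration from u0 = 0, s0 = 0 and return the final u.

    Prox-nets may also be plain callables (u, s, g) -> (u, s); substituting
    the classical update prox_{tau J}(u - tau g) recovers the unlearned
    proximal gradient method exactly.
    """
    op = net.operator
    nu = net.config.n_image_channels
    h, w = op.in_shape[-2:]
    u = np.zeros((nu, h, w))
    s = np.zeros((net.config.memory_channels, h, w))
    aty = op.adjoint(y)
    caches = []
    for i, pnet in enumerate(net.prox_nets):
        g = net.grad_scale * (
            _as_channels(op.normal(_from_channels(u, op.in_shape)), nu)
            - _as_channels(aty, nu)
        )
        if isinstance(pnet, ProxNet):
            u_new, s_new, cache = prox_net_apply(pnet, u, s, g)
        else:
            u_new, s_new = pnet(u, s, g)
            cache = None
        if not np.all(np.isfinite(u_new)):
            raise FloatingPointError(f"NaN/Inf in iterate at unrolled iteration {i + 1}")
        if return_cache:
            caches.append((u, s, g, cache))
        u, s = u_new, s_new
    out = _from_channels(u, op.in_shape)
    return (out, caches) if return_cache else out


def _loss_and_grads(net: UnrolledNet, u_true: np.ndarray, y: np.ndarray):
    """Squared-error loss for one pair and its gradient w.r.t. all parameters."""
    op = net.operator
    nu = net.config.n_image_channels
    u_hat, caches = unrolled_reconstruct(net, y, return_cache=True)
    target = _as_channels(np.asarray(u_true, dtype=float), nu)
    diff = _as_channels(u_hat, nu) - target
    loss = float(np.sum(diff * diff))
    du = 2.0 * diff
    ds = np.zeros((net.config.memory_channels,) + u_hat.shape[-2:])
    all_grads: list[dict] = [None] * net.it
    for i in range(net.it - 1, -1, -1):
        _, _, _, cache = caches[i]
        du_in, ds_in, dg, grads = prox_net_backward(net.prox_nets[i], cache, du, ds)
        # g_i = scale*(A^T A u_i - A^T y): the Jacobian w.r.t. u_i is the
        # (scaled) self-adjoint normal operator
        du = du_in + net.grad_scale * _as_channels(
            op.normal(_from_channels(dg, op.in_shape)), nu
        )
        ds = ds_in
        all_grads[i] = grads
    return loss, all_grads


class Adam:
    """Adam over a list of per-prox-net parameter trees."""

    def __init__(self, shapes, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {ln: {k: np.zeros_like(v) for k, v in lp.items()} for ln, lp in tree.items()}
            for tree in shapes
        ]
        self.v = [
            {ln: {k: np.zeros_like(v) for k, v in lp.items()} for ln, lp in tree.items()}
            for tree in shapes
        ]

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for tree, gtree, mtree, vtree in zip(params, grads, self.m, self.v):
            for ln in tree:
                for k in tree[ln]:
                    g = gtree[ln][k]
                    mtree[ln][k] = self.b1 * mtree[ln][k] + (1 - self.b1) * g
                    vtree[ln][k] = self.b2 * vtree[ln][k] + (1 - self.b2) * g * g
                    mhat = mtree[ln][k] / bc1
                    vhat = vtree[ln][k] / bc2
                    tree[ln][k] = tree[ln][k] - self.lr * mhat / (
                        np.sqrt(vhat) + self.eps
                    )


def _net_params(net: UnrolledNet):
    return [
        {ln: layer.params() for ln, layer in pnet.layers().items()}
        for pnet in net.prox_nets
    ]


def _set_net_params(net: UnrolledNet, params) -> None:
    for pnet, tree in zip(net.prox_nets, params):
        for ln, layer in pnet.layers().items():
            layer.set_params(tree[ln])


def train_erm(
    net: UnrolledNet,
    dataset,
    n_iters: int = 2000,
    lr: float = 1e-4,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    seed: int = 0,
) -> np.ndarray:
    """Empirical risk minimisation with Adam, minibatch size 1.

    Samples one training pair uniformly per iteration (deterministic given
    the seed), updates the net in place, and returns the per-iteration loss
    trace.  Aborts on a non-finite loss.
    """
    pairs = dataset.pairs() if hasattr(dataset, "pairs") else list(dataset)
    rng = np.random.default_rng(seed)
    params = _net_params(net)
    opt = Adam(params, lr=lr, beta1=beta1, beta2=beta2, eps=eps)
    trace = np.empty(n_iters)
    for i in range(n_iters):
        u_true, y = pairs[rng.integers(len(pairs))]
        loss, grads = _loss_and_grads(net, u_true, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at training iteration {i + 1}")
        trace[i] = loss
        opt.step(params, grads)
        _set_net_params(net, params)
    return trace


def erm_loss(net: UnrolledNet, dataset) -> float:
    """(1/N) sum ||u_i - Phi(y_i)||^2 over a dataset."""
    pairs = dataset.pairs() if hasattr(dataset, "pairs") else list(dataset)
    total = 0.0
    for u_true, y in pairs:
        diff = unrolled_reconstruct(net, y) - u_true
        total += float(np.sum(diff * diff))
    return total / len(pairs)


def subsumption_embed(net: UnrolledNet) -> UnrolledNet:
    """Embed an equivariant net into the ordinary parameterisation.

    Copies every expanded kernel and tied bias into unconstrained layers; the
    resulting net follows the identical arithmetic path, so outputs agree
    bit-for-bit.
    """
    if net.flavour != "equivariant":
        raise ValueError("subsumption embedding expects an equivariant net")
    nets = []
    for pnet in net.prox_nets:
        layers = {}
        for ln, adapter in pnet.layers().items():
            eq = adapter.layer
            layers[ln] = OrdinaryConvLayer(
                kernel=expand_kernel(eq),
                bias=eq.bias_vector(),
                padding=eq.padding,
            )
        nets.append(
            ProxNet(
                lift=layers["lift"],
                intermediate=layers["intermediate"],
                project=layers["project"],
                n_image_channels=pnet.n_image_channels,
                slope=pnet.slope,
            )
        )
    return UnrolledNet(
        prox_nets=nets,
        operator=net.operator,
        config=net.config,
        flavour="ordinary",
        grad_scale=net.grad_scale,
    )


# ---------------------------------------------------------------------------
# Checkpoint serialisation (HDF5)
# ---------------------------------------------------------------------------


def save_checkpoint(path, net: UnrolledNet, extra: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        cfg = net.config
        f.attrs.update(
            modality=cfg.modality,
            flavour=net.flavour,
            group_order=cfg.group_order,
            width_product=cfg.width_product,
            it=cfg.it,
            memory_channels=cfg.memory_channels,
            kernel_size=cfg.kernel_size,
            padding=cfg.padding,
            slope=cfg.slope,
            grad_scale=net.grad_scale,
        )
        for key, val in (extra or {}).items():
            f.attrs[key] = val
        for i, tree in enumerate(_net_params(net)):
            for ln, lp in tree.items():
                for k, v in lp.items():
                    f.create_dataset(f"proxnet{i}/{ln}/{k}", data=v)


def load_checkpoint(path, operator: LinearOperatorPair) -> UnrolledNet:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = NetConfig(
            modality=str(f.attrs["modality"]),
            group_order=int(f.attrs["group_order"]),
            width_product=int(f.attrs["width_product"]),
            it=int(f.attrs["it"]),
            memory_channels=int(f.attrs["memory_channels"]),
            kernel_size=int(f.attrs["kernel_size"]),
            padding=str(f.attrs["padding"]),
            slope=float(f.attrs["slope"]),
            grad_scale=float(f.attrs["grad_scale"]),
        )
        net = build_net(str(f.attrs["flavour"]), cfg, operator, seed=0)
        params = _net_params(net)
        for i, tree in enumerate(params):
            for ln, lp in tree.items():
                for k in lp:
                    lp[k] = f[f"proxnet{i}/{ln}/{k}"][()]
        _set_net_params(net, params)
    return net
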