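"""The recurrent graph network.

A single message-passing block is applied ``K`` times to an encoded
input graph, so depth (the receptive field) grows without adding
parameters. At step ``k`` the latent input graph — node latents ``v'``
and edge latents ``e'``, produced once by dense+ReLU encoders — is
concatenated with the hidden state ``(u^k, f^k)`` (initialized to
zeros). Hidden edges are updated from the concatenated endpoint and
edge vectors; hidden nodes are updated from the *sum of incident
updated edge messages only* — the previous node hidden state is not
concatenated back in, which keeps the update focused on the immediate
structural context:

    f_ij^{k+1} = phi([u~_i^k, u~_j^k, f~_ij^k])
    u_i^{k+1}  = psi(sum_{j in N_i} f_ij^{k+1})

with ``u~ = [v', u]`` and ``f~ = [e', f]``. A shared linear decoder
maps hidden node features at every step to a per-localization 2D
displacement (in units of the graph feature scale, multiplied back to
nm), optionally alongside per-node class logits.

Everything — including backpropagation through the recurrence — is
implemented on plain numpy arrays; gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass
from io import BytesIO

import numpy as np

from ._rng import substream
from .graph import PointGraph

__all__ = [
    "ModelConfig",
    "init_params",
    "count_parameters",
    "encode",
    "miro_step",
    "decode",
    "forward",
    "backward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    hidden_dim : width H of latent and hidden node/edge vectors
        (256 by default; 64 already performs respectably).
    n_steps : number of recurrent applications K of the block.
    n_eig : input node-feature width; must match the graph builder.
    n_classes : class-decoder width (0 disables classification; when
        enabled, class 0 is the explicit background class).
    k_star : step index where multiscale targets switch from the fine
        to the coarse scale (0 = single-scale).
    seed : weight-initialization seed.
    """

    hidden_dim: int = 256
    n_steps: int = 15
    n_eig: int = 5
    n_classes: int = 0
    k_star: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1 or self.n_steps < 1 or self.n_eig < 1:
            raise ValueError("hidden_dim, n_steps and n_eig must be >= 1")
        if not (0 <= self.k_star <= self.n_steps):
            raise ValueError("k_star must lie in [0, n_steps]")


# layer name -> (in_width, out_width) as functions of (n_eig, H, n_classes)
def _layer_shapes(cfg: ModelConfig) -> dict[str, tuple[int, int]]:
    H = cfg.hidden_dim
    shapes = {
        "node_enc": (cfg.n_eig, H),
        "edge_enc": (3, H),
        "phi": (6 * H, H),   # [u~_i, u~_j, f~_ij], each of width 2H
        "psi": (H, H),
        "dec": (H, 2),
    }
    if cfg.n_classes:
        shapes["cls"] = (H, cfg.n_classes)
    return shapes


def init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    """Initialize weights with uniform fan-in scaling (seeded)."""
    rng = substream(cfg.seed, "init")
    params = {}
    for name, (fan_in, fan_out) in _layer_shapes(cfg).items():
        bound = 1.0 / np.sqrt(fan_in)
        params[f"{name}_W"] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        params[f"{name}_b"] = rng.uniform(-bound, bound, size=fan_out)
    return params


def count_parameters(params: dict[str, np.ndarray]) -> int:
    """Exact number of learnable scalars (independent of n_steps)."""
    return int(sum(p.size for p in params.values()))


def _relu(x):
    return np.maximum(x, 0.0)


def encode(graph: PointGraph, params, cfg: ModelConfig):
    """Map input node/edge features to width-H latents (dense + ReLU)."""
    if graph.node_features.shape[1] != cfg.n_eig:
        raise ValueError(
            f"graph has {graph.node_features.shape[1]} node features, "
            f"model expects n_eig={cfg.n_eig}"
        )
    vp = _relu(graph.node_features @ params["node_enc_W"] + params["node_enc_b"])
    ep = _relu(graph.edge_features @ params["edge_enc_W"] + params["edge_enc_b"])
    return vp, ep


def miro_step(vp, ep, u, f, edges, params):
    """One application of the recurrent block.

    Returns the updated hidden state ``(u', f')`` plus the aggregated
    message matrix and phi input needed for backpropagation. The latent
    graph ``(vp, ep)`` is read but never modified.
    """
    src, dst = edges[:, 0], edges[:, 1]
    ut = np.hstack([vp, u])                       # (N, 2H)
    ft = np.hstack([ep, f])                       # (E, 2H)
    phi_in = np.hstack([ut[src], ut[dst], ft])    # (E, 6H)
    f_new = _relu(phi_in @ params["phi_W"] + params["phi_b"])
    agg = np.zeros_like(u)
    np.add.at(agg, src, f_new)                    # u_i aggregates f_ij over j in N_i
    u_new = _relu(agg @ params["psi_W"] + params["psi_b"])
    return u_new, f_new, agg, phi_in


def decode(u, params, feature_scale, n_classes=0):
    """Linear decoders: hidden node features -> displacement (nm) [+ logits]."""
    r = (u @ params["dec_W"] + params["dec_b"]) * feature_scale
    c = u @ params["cls_W"] + params["cls_b"] if n_classes else None
    return r, c


def forward(graph: PointGraph, params, cfg: ModelConfig, keep_cache: bool = False):
    """Run K recurrent steps, decoding after each.

    Returns a dict with per-step displacement predictions ``r`` (list of
    (N, 2) nm arrays), per-step class logits ``logits`` (or None), the
    final hidden node features ``u_final``, and — when ``keep_cache`` —
    the intermediates needed by :func:`backward`.
    """
    N, E, H = graph.n_nodes, graph.n_edges, cfg.hidden_dim
    vp, ep = encode(graph, params, cfg)
    u = np.zeros((N, H))
    f = np.zeros((E, H))
    r_steps, c_steps, cache = [], [], []
    for _ in range(cfg.n_steps):
        u_new, f_new, agg, phi_in = miro_step(vp, ep, u, f, graph.edges, params)
        r, c = decode(u_new, params, graph.feature_scale, cfg.n_classes)
        r_steps.append(r)
        c_steps.append(c)
        if keep_cache:
            cache.append((u, f, u_new, f_new, agg, phi_in))
        u, f = u_new, f_new
    out = {
        "r": r_steps,
        "logits": c_steps if cfg.n_classes else None,
        "u_final": u,
        "vp": vp,
        "ep": ep,
    }
    if keep_cache:
        out["cache"] = cache
    return out


def backward(graph: PointGraph, params, cfg: ModelConfig, out,
             grad_r, grad_logits=None) -> dict[str, np.ndarray]:
    """Backpropagate per-step output gradients through the recurrence.

    Parameters
    ----------
    out : dict
        Result of :func:`forward` with ``keep_cache=True``.
    grad_r : list of (N, 2) arrays
        d(loss)/d(displacement) per step, displacement in nm.
    grad_logits : list of (N, n_classes) arrays, optional
        d(loss)/d(logits) per step.

    Returns
    -------
    dict mapping parameter names to gradient arrays.
    """
    edges = graph.edges
    src, dst = edges[:, 0], edges[:, 1]
    H = cfg.hidden_dim
    scale = graph.feature_scale
    vp, ep, cache = out["vp"], out["ep"], out["cache"]

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    g_vp = np.zeros_like(vp)
    g_ep = np.zeros_like(ep)
    gu_state = np.zeros((graph.n_nodes, H))   # grad wrt u entering step k+1
    gf_state = np.zeros((graph.n_edges, H))

    for k in range(cfg.n_steps - 1, -1, -1):
        u_prev, f_prev, u_new, f_new, agg, phi_in = cache[k]
        gu = gu_state + (grad_r[k] * scale) @ params["dec_W"].T
        grads["dec_W"] += u_new.T @ (grad_r[k] * scale)
        grads["dec_b"] += (grad_r[k] * scale).sum(0)
        if grad_logits is not None and grad_logits[k] is not None:
            gu += grad_logits[k] @ params["cls_W"].T
            grads["cls_W"] += u_new.T @ grad_logits[k]
            grads["cls_b"] += grad_logits[k].sum(0)
        # u_new = relu(agg @ psi_W + psi_b)
        gz_u = gu * (u_new > 0)
        grads["psi_W"] += agg.T @ gz_u
        grads["psi_b"] += gz_u.sum(0)
        g_agg = gz_u @ params["psi_W"].T
        # agg[i] = sum of f_new over edges with src == i
        gf = g_agg[src] + gf_state
        gz_f = gf * (f_new > 0)
        grads["phi_W"] += phi_in.T @ gz_f
        grads["phi_b"] += gz_f.sum(0)
        g_phi_in = gz_f @ params["phi_W"].T          # (E, 6H)
        g_ut = np.zeros((graph.n_nodes, 2 * H))
        np.add.at(g_ut, src, g_phi_in[:, : 2 * H])
        np.add.at(g_ut, dst, g_phi_in[:, 2 * H: 4 * H])
        g_ft = g_phi_in[:, 4 * H:]
        g_vp += g_ut[:, :H]
        gu_state = g_ut[:, H:]
        g_ep += g_ft[:, :H]
        gf_state = g_ft[:, H:]

    # u^0 and f^0 are zeros: gradients into them vanish
    gz_vp = g_vp * (vp > 0)
    grads["node_enc_W"] += graph.node_features.T @ gz_vp
    grads["node_enc_b"] += gz_vp.sum(0)
    gz_ep = g_ep * (ep > 0)
    grads["edge_enc_W"] += graph.edge_features.T @ gz_ep
    grads["edge_enc_b"] += gz_ep.sum(0)
    return grads


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict[str, np.ndarray], cfg: ModelConfig,
                    graph_config: dict | None = None) -> None:
    """Save a model to a single zip archive (config JSON + weight arrays)."""
    meta = {"model": asdict(cfg), "graph": graph_config or {}}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        buf = BytesIO()
        np.savez(buf, **params)
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path):
    """Load a checkpoint; returns (params, ModelConfig, graph_config dict)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        with zf.open("params.npz") as fh:
            npz = np.load(BytesIO(fh.read()))
            params = {k: npz[k] for k in npz.files}
    cfg = ModelConfig(**meta["model"])
    expected = _layer_shapes(cfg)
    for name, (fi, fo) in expected.items():
        if params[f"{name}_W"].shape != (fi, fo):
            raise ValueError(f"checkpoint layer {name} has wrong shape")
    return params, cfg, meta.get("graph", {})
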