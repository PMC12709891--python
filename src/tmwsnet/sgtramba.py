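"""Hybrid grouped-attention / state-space feature extraction.

The block runs in three steps:

1. *Grouping*: farthest-point sampling seeds G group centers; each group is
   the center's k nearest neighbours.
2. *Intra-group attention*: multi-head attention within each group whose
   value vectors are modulated by a learned relative-position code.  The code
   is a small perceptron over the raw displacement concatenated with its
   sine/cosine encoding at dyadic frequencies 2^i — the "Fourier-enhanced"
   geometric pathway that sharpens sensitivity to fine spatial offsets.
3. *Inter-group sequence modeling*: a learned importance score orders the
   group features in descending and ascending order; both sequences pass
   through a stack of selective state-space (Mamba-style) layers with shared
   weights and the two outputs are averaged, giving linear-cost global
   context across groups.

Per-point outputs are the attention outputs plus each group's post-sequence
feature broadcast back to its members (averaged when a point belongs to
several groups); the global feature is a max-pool over groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Parameter, Tensor, concatenate, segment_sum
from .nn import BatchNorm1d, LayerNorm, Linear, MLP, Module

__all__ = [
    "GroupSet", "fps", "group_points", "fourier_code",
    "GroupedAttention", "grouped_attention",
    "importance_scores", "bidirectional_order",
    "ssm_scan", "SSMLayer", "MambaLayer", "mamba_layer",
    "SGTrambaBlock", "sgtramba_forward",
]


# ---------------------------------------------------------------------------
# grouping


def fps(coords: np.ndarray, G: int, start: int = 0) -> np.ndarray:
    """Farthest-point sampling: greedy max-min selection, ties to lowest index."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if not 1 <= G <= n:
        raise ValueError(f"G must be in [1, N={n}], got {G}")
    chosen = np.empty(G, dtype=np.int64)
    chosen[0] = start
    mind = np.linalg.norm(coords - coords[start], axis=1)
    for i in range(1, G):
        nxt = int(np.argmax(mind))  # argmax returns the first (lowest) index
        chosen[i] = nxt
        mind = np.minimum(mind, np.linalg.norm(coords - coords[nxt], axis=1))
    return chosen


@dataclass
class GroupSet:
    """G groups of k points each, with features gathered per member."""

    centers: np.ndarray        # G x 3
    center_idx: np.ndarray     # G
    member_idx: np.ndarray     # G x k
    member_coords: np.ndarray  # G x k x 3
    member_feats: object       # G x k x c (Tensor or ndarray)


def _lex_lowest(coords: np.ndarray) -> int:
    """Index of the lexicographically smallest coordinate row (grouping seed)."""
    return int(np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))[0])


def group_points(coords: np.ndarray, feats, G: int, k: int) -> GroupSet:
    """FPS centers + k nearest neighbours per center (center always included)."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if k > n:
        raise ValueError(f"k={k} exceeds N={n}")
    centers = fps(coords, G, start=_lex_lowest(coords))
    d = np.linalg.norm(coords[centers][:, None, :] - coords[None, :, :], axis=2)
    # sort by (distance, index): deterministic tie-break to the lowest index
    order = np.lexsort((np.broadcast_to(np.arange(n), (G, n)), d), axis=1)
    member_idx = order[:, :k]
    member_feats = feats[member_idx] if isinstance(feats, Tensor) else np.asarray(feats)[member_idx]
    return GroupSet(
        centers=coords[centers],
        center_idx=centers,
        member_idx=member_idx,
        member_coords=coords[member_idx],
        member_feats=member_feats,
    )


def fourier_code(delta: np.ndarray, L: int) -> np.ndarray:
    """sin/cos of each displacement axis at frequencies 2^i, i = 0..L-1.

    Output length is 6L for a 3-vector (works batched on (..., 3) input).
    """
    delta = np.asarray(delta, dtype=np.float64)
    if L == 0:
        return np.zeros(delta.shape[:-1] + (0,))
    freqs = 2.0 ** np.arange(L)
    ang = delta[..., :, None] * freqs  # (..., 3, L)
    code = np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)  # (..., 3, 2L)
    return code.reshape(delta.shape[:-1] + (6 * L,))


# ---------------------------------------------------------------------------
# intra-group attention


class GroupedAttention(Module):
    """Multi-head attention within groups with position-modulated values.

    Channels are split into ``n_heads`` slices; per head, attention logits
    are scaled dot products of center-projected queries and keys, and values
    are elementwise-modulated by a perceptron over the relative position and
    its Fourier code before the weighted sum.
    """

    def __init__(self, c: int, n_heads: int, L: int, rng: np.random.Generator,
                 pos_hidden: int = 32):
        super().__init__()
        if c % n_heads:
            raise ValueError("channel count must be divisible by n_heads")
        if L < 0:
            raise ValueError("L must be >= 0")
        self.c, self.g, self.L = c, n_heads, L
        self.W_Q = Parameter(rng.standard_normal((c, c)) / np.sqrt(c))
        self.W_K = Parameter(rng.standard_normal((c, c)) / np.sqrt(c))
        self.W_V = Parameter(rng.standard_normal((c, c)) / np.sqrt(c))
        self.pos_mlp = MLP(3 + 6 * L, pos_hidden, c, rng)

    def __call__(self, member_coords: np.ndarray, member_feats: Tensor):
        """(G,k,3) coords + (G,k,c) feats -> (G,k,c) outputs, (G,c) group feats."""
        Gn, k, c = member_feats.shape
        g, hd = self.g, c // self.g
        q = member_feats @ self.W_Q
        kk = member_feats @ self.W_K
        v = member_feats @ self.W_V
        # relative position code for every ordered pair in each group
        delta = member_coords[:, :, None, :] - member_coords[:, None, :, :]
        code = np.concatenate([delta, fourier_code(delta, self.L)], axis=-1)
        pos = self.pos_mlp(Tensor(code))                      # G,k,k,c
        vprime = v.reshape(Gn, 1, k, c) * pos                 # G,k(q),k(kv),c
        # heads
        qh = q.reshape(Gn, k, g, hd).transpose(0, 2, 1, 3)    # G,g,k,hd
        kh = kk.reshape(Gn, k, g, hd).transpose(0, 2, 3, 1)   # G,g,hd,k
        logits = (qh @ kh) * (1.0 / np.sqrt(hd))              # G,g,k,k
        attn = logits.softmax(axis=-1)
        vh = vprime.reshape(Gn, k, k, g, hd).transpose(0, 3, 1, 2, 4)  # G,g,kq,kv,hd
        out = (attn.reshape(Gn, g, k, k, 1) * vh).sum(axis=3)          # G,g,k,hd
        out = out.transpose(0, 2, 1, 3).reshape(Gn, k, c)
        group_feat = out.max(axis=1)                                    # G,c
        return out, group_feat


def grouped_attention(member_coords: np.ndarray, member_feats, params: GroupedAttention):
    """Functional single-group form: (k,3), (k,c) -> ((k,c) outputs, (c,) feat)."""
    feats = member_feats if isinstance(member_feats, Tensor) else Tensor(member_feats)
    out, gf = params(member_coords[None], feats.reshape(1, *feats.shape))
    return out.reshape(feats.shape), gf.reshape(feats.shape[-1])


# ---------------------------------------------------------------------------
# importance ordering


class ImportanceScore(Module):
    """S_p = ReLU(BN(F_p W_i)): a learned non-negative score per group."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.W_i = Parameter(rng.standard_normal((c, 1)) / np.sqrt(c))
        self.bn = BatchNorm1d(1)

    def __call__(self, group_feats: Tensor) -> Tensor:
        return self.bn(group_feats @ self.W_i).relu()


def importance_scores(group_feats, W_i, bn: BatchNorm1d) -> Tensor:
    """Functional form of the score head (always >= 0)."""
    gf = group_feats if isinstance(group_feats, Tensor) else Tensor(group_feats)
    w = W_i if isinstance(W_i, Tensor) else Tensor(W_i)
    return bn(gf @ w).relu()


def bidirectional_order(scores: np.ndarray):
    """Stable descending and ascending orders (ties by original index)."""
    scores = np.asarray(scores).reshape(-1)
    asc = np.argsort(scores, kind="stable")
    desc = np.argsort(-scores, kind="stable")
    return desc, asc


# ---------------------------------------------------------------------------
# state-space sequence layers


class SSMLayer(Module):
    """Selective scan: input-dependent step size and B/C projections.

    Per channel, the diagonal recurrence is
    ``h_t = exp(dt_t * A) h_{t-1} + dt_t * B_t u_t``, ``y_t = C_t h_t`` with
    ``A`` negative real (so ``exp(dt*A)`` lies in (0,1)) and ``dt`` produced
    from the input through a softplus.
    """

    def __init__(self, c: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.c, self.d = c, d
        self.A_log = Parameter(np.log(np.tile(np.arange(1, d + 1, dtype=np.float64), (c, 1))))
        self.W_dt = Linear(c, c, rng)
        self.W_B = Linear(c, d, rng, bias=False)
        self.W_C = Linear(c, d, rng, bias=False)

    def __call__(self, u: Tensor) -> Tensor:
        T, c = u.shape
        A = -(self.A_log.exp())                       # c x d, negative
        dt = _softplus(self.W_dt(u))                  # T x c
        B = self.W_B(u)                               # T x d
        C = self.W_C(u)                               # T x d
        h = Tensor(np.zeros((c, self.d)))
        ys = []
        for t in range(T):
            dt_t = dt[t].reshape(c, 1)
            decay = (dt_t * A).exp()
            h = decay * h + (dt_t * B[t].reshape(1, self.d)) * u[t].reshape(c, 1)
            ys.append((h * C[t].reshape(1, self.d)).sum(axis=1).reshape(1, c))
        return concatenate(ys, axis=0)


def _softplus(x: Tensor) -> Tensor:
    return (x.exp() + 1.0).log()


def ssm_scan(u, layer: SSMLayer) -> Tensor:
    """Functional form of the selective scan (T x c -> T x c)."""
    u = u if isinstance(u, Tensor) else Tensor(u)
    return layer(u)


class CausalDWConv(Module):
    """Causal depthwise convolution along the sequence axis."""

    def __init__(self, c: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        w = np.zeros((kernel, c))
        w[0] = 1.0  # identity at init
        self.w = Parameter(w + rng.standard_normal((kernel, c)) * 0.02)

    def __call__(self, x: Tensor) -> Tensor:
        T, c = x.shape
        pad = Tensor(np.zeros((self.kernel - 1, c)))
        xp = concatenate([pad, x], axis=0)
        out = None
        for j in range(self.kernel):
            term = xp[self.kernel - 1 - j: self.kernel - 1 - j + T] * self.w[j]
            out = term if out is None else out + term
        return out


class MambaLayer(Module):
    """One gated SSM layer with residual connection.

    ``z = DW_Conv(MLP(LN(x)))``; the scan output is re-projected and gated by
    a SiLU branch of the normalised input; the result is added residually.
    ``zero_init=True`` zeroes the branch's output projection so the layer is
    exactly the identity at initialisation.
    """

    def __init__(self, c: int, d: int, rng: np.random.Generator,
                 kernel: int = 4, zero_init: bool = False):
        super().__init__()
        self.ln_in = LayerNorm(c)
        self.ln_gate = LayerNorm(c)
        self.ln_post = LayerNorm(c)
        self.mlp_in = MLP(c, c, c, rng)
        self.conv = CausalDWConv(c, kernel, rng)
        self.ssm = SSMLayer(c, d, rng)
        self.mlp_out = MLP(c, c, c, rng, zero_init=zero_init)

    def __call__(self, x: Tensor) -> Tensor:
        z = self.conv(self.mlp_in(self.ln_in(x)))
        F_n = self.mlp_out(self.ln_post(self.ssm(z.silu()))) * self.ln_gate(x).silu()
        return F_n + x


def mamba_layer(F_prev, layer: MambaLayer) -> Tensor:
    F_prev = F_prev if isinstance(F_prev, Tensor) else Tensor(F_prev)
    return layer(F_prev)


# ---------------------------------------------------------------------------
# full block


class SGTrambaBlock(Module):
    """Group -> intra-group attention -> importance ordering -> SSM stack.

    ``use_mamba=False`` degrades the block to plain grouped attention (the
    backbone ablation arm); ``L=0`` removes the Fourier positional pathway.
    """

    def __init__(self, c: int, rng: np.random.Generator, G: int = 64, k: int = 16,
                 n_heads: int = 4, L: int = 3, M: int = 2, d_state: int = 16,
                 use_mamba: bool = True, zero_init: bool = False):
        super().__init__()
        self.G, self.k = G, k
        self.use_mamba = use_mamba
        self.attn = GroupedAttention(c, n_heads, L, rng)
        self.score = ImportanceScore(c, rng)
        self.layers = [MambaLayer(c, d_state, rng, zero_init=zero_init)
                       for _ in range(M)]
        self.out_proj = Linear(2 * c, c, rng, zero_init=zero_init)

    def __call__(self, coords: np.ndarray, feats: Tensor):
        """(N,3), (N,c) -> (point_feats (N,c), global_feat (c,))."""
        n, c = feats.shape
        G = min(self.G, n)
        k = min(self.k, n)
        gs = group_points(coords, feats, G, k)
        attn_out, group_feat = self.attn(gs.member_coords, gs.member_feats)
        scores = self.score(group_feat)
        desc, asc = bidirectional_order(scores.data)
        if self.use_mamba:
            outs = []
            for order in (desc, asc):
                seq = group_feat[order]
                for layer in self.layers:
                    seq = layer(seq)
                outs.append(seq[np.argsort(order)])
            group_out = (outs[0] + outs[1]) * 0.5
        else:
            group_out = group_feat
        global_feat = group_out.max(axis=0)
        # broadcast back to points: attention output + group feature, averaged
        # over the groups containing each point
        flat_idx = gs.member_idx.reshape(-1)
        contrib = attn_out.reshape(G * k, c) + group_out[np.repeat(np.arange(G), k)]
        sums = segment_sum(contrib, flat_idx, n)
        counts = np.bincount(flat_idx, minlength=n).astype(np.float64)
        covered = counts > 0
        inv = np.where(covered, 1.0 / np.maximum(counts, 1), 0.0)
        point_feats = sums * Tensor(inv[:, None])
        if not covered.all():
            # points missed by every group get their nearest center's feature
            orphan = np.where(~covered)[0]
            _, nearest = cKDTree(gs.centers).query(coords[orphan])
            fill = np.zeros((n, 1))
            fill[orphan] = 1.0
            scatter = np.zeros((n, G))
            scatter[orphan, np.atleast_1d(nearest)] = 1.0
            point_feats = point_feats + Tensor(scatter) @ group_out
        # residual mixing of the block output with its input
        mixed = self.out_proj(concatenate([feats, point_feats], axis=1))
        return feats + mixed, global_feat


def sgtramba_forward(coords: np.ndarray, feats, block: SGTrambaBlock):
    """(N,3), (N,c) -> (N,c point features, (c,) global feature)."""
    feats = feats if isinstance(feats, Tensor) else Tensor(feats)
    return block(coords, feats)
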