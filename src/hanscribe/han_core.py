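"""Hierarchical attention network: forward pass, loss, and analytic gradients.

Architecture (per document): embed tokens -> bidirectional GRU over the
words of each sentence -> word-level attention pooling into sentence
vectors -> bidirectional GRU over sentences -> sentence-level attention
pooling into a document vector -> softmax over {CTRL, AD}.

The GRU cell uses the standard gate formulation

    z = sigma(x W_z + h U_z + b_z)           (update gate)
    r = sigma(x W_r + h U_r + b_r)           (reset gate)
    c = tanh(x W_c + (r * h) U_c + b_c)      (candidate state)
    h' = (1 - z) * h + z * c

and attention pooling over hidden states H with mask m is

    s_t = tanh(W^T h_t + b),  e_t = s_t . u_ctx,
    a = softmax(e over valid t),  pooled = sum_t a_t h_t.

Everything is plain numpy; the backward pass is hand-derived and verified
against central finite differences in the test suite.  Masked (padded)
positions never influence outputs or gradients: the recurrences gate their
state updates on the mask and attention assigns padded positions zero
weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.special import expit as _sigmoid

from .errors import DimensionError, EmptyDocumentError, HanscribeError, InputError
from .textprep import EmbeddingMatrix, EncodedBatch

logger = logging.getLogger(__name__)

#: floor inside log() of the loss; avoids -inf on saturated predictions
PROB_CLAMP = 1e-12

ABLATIONS = ("none", "no_word_attn", "no_sentence_attn")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GruParams:
    """One GRU direction.  Gate order inside the stacked arrays: z, r, c."""

    W: np.ndarray  # (d_in, 3u) input weights
    U: np.ndarray  # (u, 3u)    recurrent weights
    b: np.ndarray  # (3u,)      biases

    def __post_init__(self) -> None:
        u = self.U.shape[0]
        if self.U.shape != (u, 3 * u) or self.W.shape[1] != 3 * u \
                or self.b.shape != (3 * u,):
            raise DimensionError(
                f"inconsistent GRU shapes W{self.W.shape} U{self.U.shape} "
                f"b{self.b.shape}"
            )

    @property
    def hidden_size(self) -> int:
        return self.U.shape[0]

    @property
    def input_size(self) -> int:
        return self.W.shape[0]

    def gate(self, which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(input_weights, recurrent_weights, bias) view for gate z/r/c."""
        u = self.hidden_size
        i = {"z": 0, "r": 1, "c": 2}[which]
        sl = slice(i * u, (i + 1) * u)
        return self.W[:, sl], self.U[:, sl], self.b[sl]


@dataclass
class AttentionParams:
    """One attention level: projection (W, b) and context vector u_ctx."""

    W: np.ndarray      # (2u, a)
    b: np.ndarray      # (a,)
    u_ctx: np.ndarray  # (a,)

    def __post_init__(self) -> None:
        a = self.W.shape[1]
        if self.b.shape != (a,) or self.u_ctx.shape != (a,):
            raise DimensionError(
                f"attention shapes W{self.W.shape} b{self.b.shape} "
                f"u_ctx{self.u_ctx.shape} inconsistent"
            )


@dataclass
class HanParams:
    """Every learnable array of the model."""

    embedding: EmbeddingMatrix
    word_fwd: GruParams
    word_bwd: GruParams
    sent_fwd: GruParams
    sent_bwd: GruParams
    word_attn: AttentionParams
    sent_attn: AttentionParams
    classifier_w: np.ndarray  # (2, 2u)
    classifier_b: np.ndarray  # (2,)

    def flat(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (name, array) for every learnable array, fixed order."""
        yield "embedding", self.embedding.weights
        for prefix, g in (
            ("word_fwd", self.word_fwd), ("word_bwd", self.word_bwd),
            ("sent_fwd", self.sent_fwd), ("sent_bwd", self.sent_bwd),
        ):
            yield f"{prefix}.W", g.W
            yield f"{prefix}.U", g.U
            yield f"{prefix}.b", g.b
        for prefix, a in (("word_attn", self.word_attn),
                          ("sent_attn", self.sent_attn)):
            yield f"{prefix}.W", a.W
            yield f"{prefix}.b", a.b
            yield f"{prefix}.u_ctx", a.u_ctx
        yield "classifier_w", self.classifier_w
        yield "classifier_b", self.classifier_b

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {name: np.zeros_like(arr) for name, arr in self.flat()}

    def copy(self) -> "HanParams":
        import copy as _copy

        new = _copy.deepcopy(self)
        return new

    def save(self, path, header: Optional[dict] = None) -> None:
        """Checkpoint: one .npz archive of all arrays + a JSON header."""
        import json

        arrays = {name.replace(".", "__"): arr for name, arr in self.flat()}
        meta = dict(header or {})
        meta.setdefault("format", "hanscribe-checkpoint-v1")
        meta["dims"] = {
            "vocab": int(self.embedding.weights.shape[0]),
            "embed": int(self.embedding.dim),
            "gru_units": int(self.word_fwd.hidden_size),
            "attn": int(self.word_attn.W.shape[1]),
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["HanParams", dict]:
        import json

        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())

            def get(n):
                return np.array(data[n.replace(".", "__")])

            emb_w = get("embedding")
            emb = EmbeddingMatrix(weights=emb_w, dim=emb_w.shape[1])
            grus = {
                p: GruParams(W=get(f"{p}.W"), U=get(f"{p}.U"), b=get(f"{p}.b"))
                for p in ("word_fwd", "word_bwd", "sent_fwd", "sent_bwd")
            }
            attns = {
                p: AttentionParams(W=get(f"{p}.W"), b=get(f"{p}.b"),
                                   u_ctx=get(f"{p}.u_ctx"))
                for p in ("word_attn", "sent_attn")
            }
            cw, cb = get("classifier_w"), get("classifier_b")
        params = cls(embedding=emb, word_attn=attns["word_attn"],
                     sent_attn=attns["sent_attn"],
                     classifier_w=cw, classifier_b=cb, **grus)
        return params, header


@dataclass
class AttentionRecord:
    """Attention weights for one document.

    ``word_weights[i]`` is the simplex over the valid words of sentence i;
    ``sentence_weights`` the simplex over valid sentences; and
    ``normalized_word_weights[i][t] = sentence_weights[i] * word_weights[i][t]``,
    the hierarchical product that sums to 1 over the whole document and is
    what the visualization shades.
    """

    word_weights: list[np.ndarray]
    sentence_weights: np.ndarray

    @property
    def normalized_word_weights(self) -> list[np.ndarray]:
        return [m_i * w for m_i, w in zip(self.sentence_weights, self.word_weights)]

    def validate(self, atol: float = 1e-6) -> None:
        for i, w in enumerate(self.word_weights):
            if len(w) and abs(w.sum() - 1.0) > atol:
                raise InputError(f"word weights of sentence {i} sum to {w.sum()}")
        if abs(self.sentence_weights.sum() - 1.0) > atol:
            raise InputError(
                f"sentence weights sum to {self.sentence_weights.sum()}"
            )


@dataclass
class ForwardOutput:
    """Per-document result of a forward pass."""

    class_probabilities: np.ndarray  # (2,) simplex; index 1 = AD
    attention: AttentionRecord
    document_vector: np.ndarray      # (2u,)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def gru_step(x: np.ndarray, h_prev: np.ndarray, params: GruParams) -> np.ndarray:
    """One GRU update; broadcasts over leading batch dimensions."""
    x = np.asarray(x, dtype=params.W.dtype)
    h_prev = np.asarray(h_prev, dtype=params.W.dtype)
    u = params.hidden_size
    if x.shape[-1] != params.input_size or h_prev.shape[-1] != u:
        raise DimensionError(
            f"gru_step: x dim {x.shape[-1]} vs {params.input_size}, "
            f"h dim {h_prev.shape[-1]} vs {u}"
        )
    gi = x @ params.W + params.b
    z = _sigmoid(gi[..., :u] + h_prev @ params.U[:, :u])
    r = _sigmoid(gi[..., u:2 * u] + h_prev @ params.U[:, u:2 * u])
    c = np.tanh(gi[..., 2 * u:] + (r * h_prev) @ params.U[:, 2 * u:])
    return (1.0 - z) * h_prev + z * c


def _gru_scan(X: np.ndarray, mask: np.ndarray, p: GruParams,
              reverse: bool) -> tuple[np.ndarray, dict]:
    """Run one GRU direction over (N, T, d) with mask-gated state updates.

    At masked steps the hidden state is carried through unchanged, so a
    contiguous pad suffix (forward) or prefix (reversed order) is inert.
    Returns outputs zeroed at masked positions, plus the cache for backward.
    """
    N, T, d = X.shape
    u = p.hidden_size
    dt = p.W.dtype
    Z = np.empty((T, N, u), dtype=dt)
    R = np.empty((T, N, u), dtype=dt)
    C = np.empty((T, N, u), dtype=dt)
    Hprev = np.empty((T, N, u), dtype=dt)
    H = np.zeros((N, T, u), dtype=dt)
    h = np.zeros((N, u), dtype=dt)
    Uc = p.U[:, 2 * u:]
    # input projections for all timesteps in one matmul
    GI = (X.reshape(N * T, d) @ p.W + p.b).reshape(N, T, 3 * u)
    times = range(T - 1, -1, -1) if reverse else range(T)
    for t in times:
        m = mask[:, t:t + 1]
        gi = GI[:, t]
        hu = h @ p.U[:, :2 * u]  # recurrent part of z and r gates
        zr = _sigmoid(gi[:, :2 * u] + hu)
        z, r = zr[:, :u], zr[:, u:]
        c = np.tanh(gi[:, 2 * u:] + (r * h) @ Uc)
        h_new = (1.0 - z) * h + z * c
        Z[t], R[t], C[t], Hprev[t] = z, r, c, h
        h = m * h_new + (1.0 - m) * h
        H[:, t] = h
    out = H * mask[:, :, None]
    cache = {"Z": Z, "R": R, "C": C, "Hprev": Hprev}
    return out, cache


def _gru_scan_backward(dOut: np.ndarray, X: np.ndarray, mask: np.ndarray,
                       p: GruParams, cache: dict, reverse: bool,
                       ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backprop through `_gru_scan`; returns dX and parameter gradients."""
    N, T, d = X.shape
    u = p.hidden_size
    Uc = p.U[:, 2 * u:]
    Z, R, C, Hprev = cache["Z"], cache["R"], cache["C"], cache["Hprev"]
    G = np.empty((T, N, 3 * u), dtype=X.dtype)  # pre-activation gate grads
    dh = np.zeros((N, u), dtype=X.dtype)
    times = range(T - 1, -1, -1) if reverse else range(T)
    for t in reversed(list(times)):
        m = mask[:, t:t + 1]
        dht = dh + dOut[:, t] * m
        z, r, c, hp = Z[t], R[t], C[t], Hprev[t]
        dh_new = m * dht
        dhp = (1.0 - m) * dht
        # h_new = (1-z) hp + z c
        dzp = dh_new * (c - hp) * z * (1.0 - z)
        dcp = dh_new * z * (1.0 - c * c)
        dhp = dhp + dh_new * (1.0 - z)
        drh = dcp @ Uc.T
        drp = drh * hp * r * (1.0 - r)
        dhp = dhp + drh * r
        Gt = G[t]
        Gt[:, :u] = dzp
        Gt[:, u:2 * u] = drp
        Gt[:, 2 * u:] = dcp
        dhp = dhp + Gt[:, :2 * u] @ p.U[:, :2 * u].T
        dh = dhp
    # parameter and input gradients in a few large matmuls
    Gflat = G.reshape(T * N, 3 * u)
    Hp = Hprev.reshape(T * N, u)
    dW = X.transpose(1, 0, 2).reshape(T * N, d).T @ Gflat
    dU = np.empty_like(p.U)
    dU[:, :2 * u] = Hp.T @ Gflat[:, :2 * u]
    dU[:, 2 * u:] = (R.reshape(T * N, u) * Hp).T @ Gflat[:, 2 * u:]
    db = Gflat.sum(axis=0)
    dX = (Gflat @ p.W.T).reshape(T, N, d).transpose(1, 0, 2)
    return dX, {"W": dW, "U": dU, "b": db}


def bigru_encode(sequence: np.ndarray, fwd: GruParams, bwd: GruParams,
                 mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Encode one sequence (T, d) -> (T, 2u); masked positions are zero.

    The mask must mark a contiguous prefix of valid positions.
    """
    X = np.asarray(sequence, dtype=fwd.W.dtype)[None, :, :]
    T = X.shape[1]
    if mask is None:
        mask = np.ones(T, dtype=X.dtype)
    mask = np.asarray(mask, dtype=X.dtype)[None, :]
    if mask.sum() < 1:
        raise EmptyDocumentError("bigru_encode: no valid positions")
    Of, _ = _gru_scan(X, mask, fwd, reverse=False)
    Ob, _ = _gru_scan(X, mask, bwd, reverse=True)
    return np.concatenate([Of, Ob], axis=-1)[0]


def _attention_forward(H: np.ndarray, mask: np.ndarray, p: AttentionParams,
                       uniform: bool) -> tuple[np.ndarray, np.ndarray, dict]:
    """Attention pooling over (N, T, h).  Rows with no valid position give
    zero weights and a zero pooled vector (the caller masks them out)."""
    valid = mask.sum(axis=1, keepdims=True)  # (N,1)
    if uniform:
        weights = np.where(valid > 0, mask / np.maximum(valid, 1.0), 0.0)
        cache = {"uniform": True, "weights": weights}
    else:
        S = np.tanh(H @ p.W + p.b)      # (N, T, a)
        e = S @ p.u_ctx                 # (N, T)
        neg = np.finfo(H.dtype).min / 4
        e_masked = np.where(mask > 0, e, neg)
        e_max = e_masked.max(axis=1, keepdims=True)
        ex = np.exp(e_masked - e_max) * mask
        denom = ex.sum(axis=1, keepdims=True)
        tiny = np.finfo(H.dtype).tiny
        weights = np.where(denom > 0, ex / np.maximum(denom, tiny), 0.0)
        cache = {"uniform": False, "S": S, "weights": weights}
    pooled = np.einsum("nt,nth->nh", weights, H)
    return pooled, weights, cache


def _attention_backward(dPooled: np.ndarray, H: np.ndarray, mask: np.ndarray,
                        p: AttentionParams, cache: dict,
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    weights = cache["weights"]
    dH = weights[:, :, None] * dPooled[:, None, :]
    grads = {"W": np.zeros_like(p.W), "b": np.zeros_like(p.b),
             "u_ctx": np.zeros_like(p.u_ctx)}
    if cache["uniform"]:
        return dH, grads
    S = cache["S"]
    dm = np.einsum("nh,nth->nt", dPooled, H)
    de = weights * (dm - (weights * dm).sum(axis=1, keepdims=True))
    grads["u_ctx"] = np.einsum("nta,nt->a", S, de)
    dS = de[:, :, None] * p.u_ctx
    dpre = dS * (1.0 - S * S)
    grads["W"] = np.einsum("nth,nta->ha", H, dpre)
    grads["b"] = dpre.sum(axis=(0, 1))
    dH += dpre @ p.W.T
    return dH, grads


def attention_pool(H: np.ndarray, params: AttentionParams,
                   mask: Optional[np.ndarray] = None,
                   uniform: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Pool one sequence of hidden vectors (T, h) -> (pooled (h,), weights)."""
    H = np.asarray(H, dtype=params.W.dtype)
    T = H.shape[0]
    if mask is None:
        mask = np.ones(T, dtype=H.dtype)
    mask = np.asarray(mask, dtype=H.dtype)
    if mask.sum() < 1:
        raise EmptyDocumentError("attention_pool: all positions masked")
    pooled, weights, _ = _attention_forward(H[None], mask[None], params, uniform)
    return pooled[0], weights[0]


def classify(p: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Numerically stable softmax(w p + b); broadcasts over batches."""
    logits = np.asarray(p) @ np.asarray(w).T + np.asarray(b)
    if not np.all(np.isfinite(logits)):
        raise HanscribeError("non-finite classifier logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=-1, keepdims=True)


def nll_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Sum over documents of -log(probability of the true class)."""
    probabilities = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    if probabilities.shape[0] != labels.shape[0]:
        raise InputError("probabilities and labels length mismatch")
    p_true = probabilities[np.arange(len(labels)), labels]
    if np.any(p_true < PROB_CLAMP):
        logger.warning("nll_loss: clamping %d probabilities below %g",
                       int((p_true < PROB_CLAMP).sum()), PROB_CLAMP)
    return float(-np.log(np.maximum(p_true, PROB_CLAMP)).sum())


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

def _dropout_mask(rng, shape, rate, dtype):
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(dtype) / keep


def _forward(batch: EncodedBatch, params: HanParams, dropout: float,
             training: bool, rng, ablation: str) -> dict:
    """Batched forward pass; returns everything the backward pass needs."""
    if ablation not in ABLATIONS:
        raise InputError(f"unknown ablation {ablation!r}")
    We = params.embedding.weights
    dt = We.dtype
    ids = batch.token_ids
    wm = batch.word_mask.astype(dt)
    sm = batch.sentence_mask.astype(dt)
    B, L, T = ids.shape
    u = params.word_fwd.hidden_size

    X = We[ids] * wm[:, :, :, None]
    use_drop = training and dropout > 0.0
    if use_drop:
        D_emb = _dropout_mask(rng, X.shape, dropout, dt)
        X = X * D_emb
    else:
        D_emb = None

    Xw = X.reshape(B * L, T, -1)
    wmask = wm.reshape(B * L, T)
    Of, cf = _gru_scan(Xw, wmask, params.word_fwd, reverse=False)
    Ob, cb = _gru_scan(Xw, wmask, params.word_bwd, reverse=True)
    Hw = np.concatenate([Of, Ob], axis=-1)  # (B*L, T, 2u)
    if use_drop:
        D_h = _dropout_mask(rng, Hw.shape, dropout, dt)
        Hw = Hw * D_h
    else:
        D_h = None

    S, Mw, cache_wa = _attention_forward(
        Hw, wmask, params.word_attn, uniform=(ablation == "no_word_attn"))
    if use_drop:
        D_s = _dropout_mask(rng, S.shape, dropout, dt)
        S = S * D_s
    else:
        D_s = None

    Ssent = S.reshape(B, L, 2 * u)
    Osf, csf = _gru_scan(Ssent, sm, params.sent_fwd, reverse=False)
    Osb, csb = _gru_scan(Ssent, sm, params.sent_bwd, reverse=True)
    Hs = np.concatenate([Osf, Osb], axis=-1)  # (B, L, 2u)

    pvec, Ms, cache_sa = _attention_forward(
        Hs, sm, params.sent_attn, uniform=(ablation == "no_sentence_attn"))
    if use_drop:
        D_p = _dropout_mask(rng, pvec.shape, dropout, dt)
        p_drop = pvec * D_p
    else:
        D_p = None
        p_drop = pvec

    probs = classify(p_drop, params.classifier_w, params.classifier_b)
    return {
        "ids": ids, "wm": wm, "sm": sm, "B": B, "L": L, "T": T, "u": u,
        "X": X, "Xw": Xw, "wmask": wmask, "cf": cf, "cb": cb, "Hw": Hw,
        "cache_wa": cache_wa, "S": S, "Ssent": Ssent, "csf": csf,
        "csb": csb, "Hs": Hs, "cache_sa": cache_sa, "pvec": pvec,
        "p_drop": p_drop, "probs": probs, "Mw": Mw, "Ms": Ms,
        "D_emb": D_emb, "D_h": D_h, "D_s": D_s, "D_p": D_p,
    }


def _attention_records(ctx: EncodedBatch, Mw: np.ndarray, Ms: np.ndarray,
                       ) -> list[AttentionRecord]:
    B, L, T = ctx.token_ids.shape
    Mw = Mw.reshape(B, L, T)
    records = []
    for b in range(B):
        word_w = []
        sent_w = []
        for i in range(L):
            if ctx.sentence_mask[b, i] > 0:
                n = int(ctx.word_mask[b, i].sum())
                word_w.append(Mw[b, i, :n].astype(np.float64))
                sent_w.append(float(Ms[b, i]))
        records.append(AttentionRecord(
            word_weights=word_w,
            sentence_weights=np.asarray(sent_w, dtype=np.float64),
        ))
    return records


def forward_document(batch: EncodedBatch, params: HanParams,
                     dropout_rate: float = 0.0, training: bool = False,
                     seed: int = 0, ablation: str = "none",
                     ) -> list[ForwardOutput]:
    """Full forward pass; returns one :class:`ForwardOutput` per document."""
    batch.validate()
    rng = np.random.default_rng(seed)
    ctx = _forward(batch, params, dropout_rate, training, rng, ablation)
    records = _attention_records(batch, ctx["Mw"], ctx["Ms"])
    return [
        ForwardOutput(
            class_probabilities=ctx["probs"][b].astype(np.float64),
            attention=records[b],
            document_vector=ctx["pvec"][b],
        )
        for b in range(ctx["B"])
    ]


def loss_and_grads(batch: EncodedBatch, params: HanParams,
                   dropout: float = 0.0, training: bool = True,
                   rng=None, ablation: str = "none",
                   ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Loss (summed NLL) and analytic gradients for every parameter array."""
    if rng is None:
        rng = np.random.default_rng(0)
    ctx = _forward(batch, params, dropout, training, rng, ablation)
    labels = batch.labels
    if np.any(labels < 0):
        raise InputError("loss requires labeled documents")
    probs = ctx["probs"]
    loss = nll_loss(probs, labels)

    B, L, T, u = ctx["B"], ctx["L"], ctx["T"], ctx["u"]
    dt = params.embedding.weights.dtype
    grads = params.zero_grads()

    dlogits = probs.astype(dt).copy()
    dlogits[np.arange(B), labels] -= 1.0
    grads["classifier_w"] = dlogits.T @ ctx["p_drop"]
    grads["classifier_b"] = dlogits.sum(axis=0)
    dp = dlogits @ params.classifier_w
    if ctx["D_p"] is not None:
        dp = dp * ctx["D_p"]

    dHs, ga = _attention_backward(dp, ctx["Hs"], ctx["sm"],
                                  params.sent_attn, ctx["cache_sa"])
    grads["sent_attn.W"], grads["sent_attn.b"], grads["sent_attn.u_ctx"] = \
        ga["W"], ga["b"], ga["u_ctx"]

    dOsf, dOsb = dHs[..., :u], dHs[..., u:]
    dS1, gsf = _gru_scan_backward(dOsf, ctx["Ssent"], ctx["sm"],
                                  params.sent_fwd, ctx["csf"], reverse=False)
    dS2, gsb = _gru_scan_backward(dOsb, ctx["Ssent"], ctx["sm"],
                                  params.sent_bwd, ctx["csb"], reverse=True)
    for k in ("W", "U", "b"):
        grads[f"sent_fwd.{k}"] = gsf[k]
        grads[f"sent_bwd.{k}"] = gsb[k]
    dS = (dS1 + dS2).reshape(B * L, 2 * u)
    if ctx["D_s"] is not None:
        dS = dS * ctx["D_s"]

    dHw, gwa = _attention_backward(dS, ctx["Hw"], ctx["wmask"],
                                   params.word_attn, ctx["cache_wa"])
    grads["word_attn.W"], grads["word_attn.b"], grads["word_attn.u_ctx"] = \
        gwa["W"], gwa["b"], gwa["u_ctx"]
    if ctx["D_h"] is not None:
        dHw = dHw * ctx["D_h"]

    dOf, dOb = dHw[..., :u], dHw[..., u:]
    dX1, gwf = _gru_scan_backward(dOf, ctx["Xw"], ctx["wmask"],
                                  params.word_fwd, ctx["cf"], reverse=False)
    dX2, gwb = _gru_scan_backward(dOb, ctx["Xw"], ctx["wmask"],
                                  params.word_bwd, ctx["cb"], reverse=True)
    for k in ("W", "U", "b"):
        grads[f"word_fwd.{k}"] = gwf[k]
        grads[f"word_bwd.{k}"] = gwb[k]
    dX = (dX1 + dX2).reshape(B, L, T, -1)
    if ctx["D_emb"] is not None:
        dX = dX * ctx["D_emb"]
    dX = dX * ctx["wm"][:, :, :, None]

    if params.embedding.trainable:
        dWe = grads["embedding"]
        np.add.at(dWe, ctx["ids"].reshape(-1),
                  dX.reshape(-1, dX.shape[-1]))
        dWe[0, :] = 0.0  # PAD row pinned
    return loss, grads, probs
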