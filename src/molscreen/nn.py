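"""NumPy implementation of the directed-arc message-passing network.

The predictor is a message-passing encoder over directed bond arcs followed
by a feed-forward head, trained by minibatch Adam on a mean-squared-error
loss between the sigmoid-bounded output and binary activity labels.

Forward pass (one packed batch; ReLU nonlinearities throughout):

    h0_e   = relu(W_i [x_src(e) ; e_e])                    arc init
    m_e^t  = sum_{k -> src(e), k != rev(e)} h_k^{t-1}      incoming messages
    h_e^t  = relu(h0_e + W_h m_e^t)                        t = 1..depth-1
    s_v    = sum_{e -> v} h_e^{depth-1}                    atom aggregation
    a_v    = relu(W_o [x_v ; s_v])                         atom embedding
    g      = mean_v a_v  (per molecule)                    readout
    p      = sigmoid(MLP(g))                               score in (0,1)

The incoming-message sum is computed as a segment sum over arc destinations
minus the reverse arc's state, which is algebraically identical to the
neighbor-list formulation but vectorizes.  All arithmetic is float64, so
training is bit-reproducible for a fixed seed on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import PackedBatch


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _segment_sum(values: np.ndarray, segments: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, segments, values)
    return out


@dataclass
class MPNNParams:
    """All trainable arrays, keyed by name.  A plain dict underneath so the
    optimizer, serialization, and finite-difference checks share one view."""

    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "MPNNParams":
        return MPNNParams({k: v.copy() for k, v in self.arrays.items()})

    def __getitem__(self, k: str) -> np.ndarray:
        return self.arrays[k]

    def __setitem__(self, k: str, v: np.ndarray) -> None:
        self.arrays[k] = v

    def keys(self):
        return self.arrays.keys()


class MPNNRegressor:
    """Message-passing encoder + MLP head producing scores in (0, 1).

    Parameters
    ----------
    atom_fdim, bond_fdim : int
        Input feature dimensions (fixed by the featurization vocabulary).
    mp_depth : int
        Number of message-passing iterations (>= 1; 1 means arc states are
        used as initialized, with no message exchange).
    mp_hidden : int
        Dimension of arc and atom hidden states.
    head_widths : sequence of int
        Hidden-layer widths of the feed-forward head.
    seed : int
        Seed for weight initialization.
    """

    def __init__(
        self,
        atom_fdim: int,
        bond_fdim: int,
        mp_depth: int = 3,
        mp_hidden: int = 64,
        head_widths: tuple[int, ...] = (1024, 1024, 512),
        seed: int = 0,
    ):
        if mp_depth < 1:
            raise ValueError("mp_depth must be >= 1")
        self.atom_fdim = atom_fdim
        self.bond_fdim = bond_fdim
        self.mp_depth = mp_depth
        self.mp_hidden = mp_hidden
        self.head_widths = tuple(head_widths)
        rng = np.random.default_rng(seed)
        p = MPNNParams()
        h = mp_hidden
        p["Wi"] = _glorot(rng, atom_fdim + bond_fdim, h)
        p["bi"] = np.zeros(h)
        p["Wh"] = _glorot(rng, h, h)
        p["bh"] = np.zeros(h)
        p["Wo"] = _glorot(rng, atom_fdim + h, h)
        p["bo"] = np.zeros(h)
        widths = (h, *self.head_widths, 1)
        for i in range(len(widths) - 1):
            p[f"head_W{i}"] = _glorot(rng, widths[i], widths[i + 1])
            p[f"head_b{i}"] = np.zeros(widths[i + 1])
        self.params = p
        self.n_head_layers = len(widths) - 1

    # ----- forward ---------------------------------------------------------

    def forward(self, batch: PackedBatch, want_cache: bool = False):
        """Return scores (n_mols,) and, optionally, the backprop cache."""
        p = self.params
        src, dst, rev = batch.arc_src, batch.arc_dst, batch.arc_rev
        n_atoms, n_arcs = batch.n_atoms, batch.n_arcs

        Z = np.concatenate([batch.atom_features[src], batch.bond_features], axis=1)
        pre0 = Z @ p["Wi"] + p["bi"]
        h = relu(pre0)
        h0 = h
        pres, ms, hs = [], [], [h0]
        for _ in range(1, self.mp_depth):
            s = _segment_sum(h, dst, n_atoms)
            m = s[src] - h[rev] if n_arcs else s[src]
            pre = h0 + m @ p["Wh"] + p["bh"]
            h = relu(pre)
            pres.append(pre)
            ms.append(m)
            hs.append(h)

        s_atom = _segment_sum(h, dst, n_atoms)
        A = np.concatenate([batch.atom_features, s_atom], axis=1)
        pre_a = A @ p["Wo"] + p["bo"]
        h_atom = relu(pre_a)

        counts = np.bincount(batch.atom_mol, minlength=batch.n_mols).astype(float)
        g = _segment_sum(h_atom, batch.atom_mol, batch.n_mols) / counts[:, None]

        head_pre, head_act = [], [g]
        x = g
        for i in range(self.n_head_layers):
            z = x @ p[f"head_W{i}"] + p[f"head_b{i}"]
            head_pre.append(z)
            x = relu(z) if i < self.n_head_layers - 1 else z
            head_act.append(x)
        scores = sigmoid(x[:, 0])

        if not want_cache:
            return scores, None
        cache = dict(
            Z=Z, pre0=pre0, pres=pres, ms=ms, hs=hs, A=A, pre_a=pre_a,
            h_atom=h_atom, counts=counts, head_pre=head_pre, head_act=head_act,
            scores=scores, batch=batch,
        )
        return scores, cache

    def predict(self, batch: PackedBatch) -> np.ndarray:
        scores, _ = self.forward(batch, want_cache=False)
        return scores

    # ----- backward --------------------------------------------------------

    def loss_and_grads(self, batch: PackedBatch, y: np.ndarray):
        """MSE loss against {0,1} targets and gradients for every parameter."""
        p = self.params
        scores, c = self.forward(batch, want_cache=True)
        n = len(y)
        loss = float(np.mean((scores - y) ** 2))

        grads = {k: np.zeros_like(v) for k, v in p.arrays.items()}
        dscore = 2.0 * (scores - y) / n
        dz_out = dscore * scores * (1.0 - scores)  # sigmoid'

        # head backward
        dx = dz_out[:, None]
        for i in range(self.n_head_layers - 1, -1, -1):
            if i < self.n_head_layers - 1:
                dx = dx * (c["head_pre"][i] > 0)
            grads[f"head_W{i}"] += c["head_act"][i].T @ dx
            grads[f"head_b{i}"] += dx.sum(axis=0)
            dx = dx @ p[f"head_W{i}"].T
        dg = dx  # (n_mols, mp_hidden)

        # readout backward: mean pool
        batch_ = c["batch"]
        dh_atom = dg[batch_.atom_mol] / c["counts"][batch_.atom_mol, None]
        dpre_a = dh_atom * (c["pre_a"] > 0)
        grads["Wo"] += c["A"].T @ dpre_a
        grads["bo"] += dpre_a.sum(axis=0)
        dA = dpre_a @ p["Wo"].T
        ds_atom = dA[:, self.atom_fdim:]

        src, dst, rev = batch_.arc_src, batch_.arc_dst, batch_.arc_rev
        n_atoms, n_arcs = batch_.n_atoms, batch_.n_arcs
        dh = ds_atom[dst] if n_arcs else np.zeros((0, self.mp_hidden))
        dh0_acc = np.zeros_like(dh)

        for t in range(self.mp_depth - 1, 0, -1):
            dpre = dh * (c["pres"][t - 1] > 0)
            dh0_acc += dpre
            grads["Wh"] += c["ms"][t - 1].T @ dpre
            grads["bh"] += dpre.sum(axis=0)
            dm = dpre @ p["Wh"].T
            # m_e = s_prev[src_e] - h_prev[rev_e]
            ds_prev = np.zeros((n_atoms, self.mp_hidden))
            np.add.at(ds_prev, src, dm)
            dh = ds_prev[dst] - dm[rev]

        dh0 = dh + dh0_acc
        dpre0 = dh0 * (c["pre0"] > 0)
        grads["Wi"] += c["Z"].T @ dpre0
        grads["bi"] += dpre0.sum(axis=0)
        return loss, grads


class Adam:
    """Standard Adam optimizer over an :class:`MPNNParams` dict."""

    def __init__(self, params: MPNNParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params.arrays[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
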