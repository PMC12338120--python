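"""GCN members, multiscale GPCN/A-GPCN ensembles, and baseline models.

A *member* is one graph convolutional network: a stack of GCN layers

.. math:: X_m = g_m(Z X_{m-1} W_m + b_m)

with ReLU activations, whose per-layer outputs are concatenated node-wise and
fed through a node-wise dense head (sigmoid hidden layers, linear scalar
output).  The structure matrix ``Z`` is the raw graph Laplacian in the
``A - D`` convention — no normalization, no self-loop augmentation.

The GPCN couples one member per hierarchy level through composed prolongation
matrices ``P_{1,i}``:

.. math::

    \\mathrm{GPCN}(X) = \\mathrm{GCN}_1(Z_1, X)
        + \\sum_{i \\ge 2} P_{1,i}\\, \\mathrm{GCN}_i(Z_i, P_{1,i}^T X).

In the *adaptive* variant (A-GPCN) the ``P_{1,i}`` are free parameters updated
by the same gradient steps as the member weights, after orthogonal
initialization from the diffusion-distance optimization; no orthogonality is
re-imposed during training.

Baselines: plain ensembles (several members sharing the fine structure
matrix), N-GCN (one member per power ``Z^r``), and a DiffPool mirror of the
GPCN in which each projection is the row-softmaxed output of an auxiliary GCN
and coarse structure matrices follow ``Z' = S^T Z S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Var
from .hierarchy import Hierarchy

__all__ = [
    "MemberSpec",
    "Member",
    "GPCNModel",
    "EnsembleModel",
    "NGCNModel",
    "DiffPoolModel",
    "gcn_forward",
    "member_forward",
    "gpcn_forward",
    "ngcn_forward",
    "diffpool_coarsen",
]


def _dense(Z):
    if isinstance(Z, Var):
        return Z
    return Z.toarray() if sp.issparse(Z) else np.asarray(Z, dtype=float)


@dataclass(frozen=True)
class MemberSpec:
    """Widths of one member: GCN filter list and dense head (last width 1)."""

    level: int  # hierarchy level index, 0 = finest
    gcn_filters: tuple[int, ...] = (64, 64, 64)
    dense_filters: tuple[int, ...] = (256, 32, 8, 1)

    def __post_init__(self):
        if self.dense_filters[-1] != 1:
            raise ValueError("dense head must end in a single output unit")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Member:
    """Parameters of one GCN member (GCN stack + node-wise dense head)."""

    def __init__(self, spec: MemberSpec, in_features: int, rng: np.random.Generator):
        self.spec = spec
        self.in_features = in_features
        self.gcn_W: list[Var] = []
        self.gcn_b: list[Var] = []
        fan = in_features
        for width in spec.gcn_filters:
            self.gcn_W.append(Var(_glorot(rng, fan, width)))
            self.gcn_b.append(Var(np.zeros(width)))
            fan = width
        self.dense_W: list[Var] = []
        self.dense_b: list[Var] = []
        fan = sum(spec.gcn_filters)  # node-wise concat of every GCN layer output
        for width in spec.dense_filters:
            self.dense_W.append(Var(_glorot(rng, fan, width)))
            self.dense_b.append(Var(np.zeros(width)))
            fan = width

    def parameters(self) -> list[Var]:
        return self.gcn_W + self.gcn_b + self.dense_W + self.dense_b

    def named_parameters(self) -> dict[str, Var]:
        out = {}
        for i, (w, b) in enumerate(zip(self.gcn_W, self.gcn_b)):
            out[f"gcn{i}_W"], out[f"gcn{i}_b"] = w, b
        for i, (w, b) in enumerate(zip(self.dense_W, self.dense_b)):
            out[f"dense{i}_W"], out[f"dense{i}_b"] = w, b
        return out


def _as_var(x, requires_grad=False) -> Var:
    return x if isinstance(x, Var) else Var(x, requires_grad=requires_grad)


def gcn_forward(Z, X, layers: list[tuple], activation: str = "relu"):
    """Plain GCN stack: ``X_m = g(Z X_{m-1} W_m + b_m)`` layer by layer.

    ``layers`` is a list of ``(W, b)`` pairs (arrays or Vars).  Returns the
    final layer output; accepts batched ``X`` of shape ``(batch, n, F)``.
    """
    Zv, Xv = _as_var(_dense(Z)), _as_var(X)
    act = {"relu": ad.relu, "sigmoid": ad.sigmoid, "linear": ad.identity}[activation]
    H = Xv
    for W, b in layers:
        H = act(ad.add(ad.matmul(ad.matmul(Zv, H), _as_var(W)), _as_var(b)))
    return H.value if not isinstance(X, Var) else H


def member_forward(Z, X, member: Member, record: dict | None = None):
    """One member's per-node scalar predictions.

    GCN stack with ReLU; node-wise concatenation of every GCN layer's output;
    dense head with sigmoid hidden layers and a linear output unit.  If
    ``record`` is given, the first GCN layer's pre-activation Var is stored
    under ``"A1"`` (used by the closed-form input-gradient machinery).
    """
    Zv = _as_var(_dense(Z))
    Xv = _as_var(X)
    H = Xv
    layer_outputs = []
    for i, (W, b) in enumerate(zip(member.gcn_W, member.gcn_b)):
        A = ad.add(ad.matmul(ad.matmul(Zv, H), W), b)
        if i == 0 and record is not None:
            record["A1"] = A
        H = ad.relu(A)
        layer_outputs.append(H)
    D = ad.concat(layer_outputs, axis=-1)
    n_dense = len(member.dense_W)
    for i, (W, b) in enumerate(zip(member.dense_W, member.dense_b)):
        D = ad.add(ad.matmul(D, W), b)
        if i < n_dense - 1:
            D = ad.sigmoid(D)  # output layer stays linear
    return D.value if not isinstance(X, Var) else D


class GPCNModel:
    """Multiscale GCN ensemble coupled by prolongation matrices.

    ``members[0]`` operates at the finest level; ``projections[i]`` holds the
    composed map P_{1,i+1} for member ``i+1``.  When ``adaptive`` the
    projections are trainable parameters.
    """

    def __init__(
        self,
        hierarchy: Hierarchy,
        member_specs: list[MemberSpec],
        in_features: int,
        adaptive: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if len(member_specs) > hierarchy.n_levels:
            raise ValueError("more members than hierarchy levels")
        rng = rng if rng is not None else np.random.default_rng()
        self.hierarchy = hierarchy
        self.adaptive = adaptive
        self.members = [Member(spec, in_features, rng) for spec in member_specs]
        self.structure_matrices = [
            Var(hierarchy.structure_matrices[s.level], requires_grad=False)
            for s in member_specs
        ]
        self.projections: list[Var] = [
            Var(hierarchy.composed_map(spec.level).copy(), requires_grad=adaptive)
            for spec in member_specs[1:]
        ]

    @property
    def n_levels(self) -> int:
        return len(self.members)

    def parameters(self) -> list[Var]:
        params = [p for m in self.members for p in m.parameters()]
        if self.adaptive:
            params += self.projections
        return params

    def level_parameters(self, level: int) -> list[Var]:
        """Trainable parameters of one level (its member, plus its P if adaptive)."""
        params = list(self.members[level].parameters())
        if self.adaptive and level >= 1:
            params.append(self.projections[level - 1])
        return params

    def forward(self, X, records: list[dict] | None = None) -> Var:
        Xv = _as_var(X)
        recs = records if records is not None else [None] * len(self.members)
        out = member_forward(self.structure_matrices[0], Xv, self.members[0], recs[0])
        for i, member in enumerate(self.members[1:]):
            P = self.projections[i]
            X_coarse = ad.matmul(ad.transpose(P), Xv)
            Y_coarse = member_forward(
                self.structure_matrices[i + 1], X_coarse, member, recs[i + 1]
            )
            out = ad.add(out, ad.matmul(P, Y_coarse))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(_as_var(np.asarray(X))).value


def gpcn_forward(model: GPCNModel, X):
    """Fine-scale predictions of the ensemble (Var in -> Var out)."""
    out = model.forward(_as_var(X))
    return out.value if not isinstance(X, Var) else out


class EnsembleModel:
    """Plain sum-of-members ensemble; every member sees the fine Z and X."""

    def __init__(self, Z, member_specs, in_features, rng=None):
        rng = rng if rng is not None else np.random.default_rng()
        self.Z = Var(_dense(Z), requires_grad=False)
        self.members = [Member(s, in_features, rng) for s in member_specs]

    def parameters(self):
        return [p for m in self.members for p in m.parameters()]

    def level_parameters(self, level: int):
        return self.members[level].parameters() if level == 0 else []

    @property
    def n_levels(self):
        return 1  # single-scale: every member is fine-scale

    def forward(self, X) -> Var:
        Xv = _as_var(X)
        out = member_forward(self.Z, Xv, self.members[0])
        for m in self.members[1:]:
            out = ad.add(out, member_forward(self.Z, Xv, m))
        return out

    def predict(self, X):
        return self.forward(_as_var(np.asarray(X))).value


class NGCNModel(EnsembleModel):
    """N-GCN: one member per structure-matrix power Z^r, r in ``radii``."""

    def __init__(self, Z, radii, member_specs, in_features, rng=None):
        if len(radii) != len(member_specs):
            raise ValueError("one member spec per radius")
        if any(r < 1 for r in radii):
            raise ValueError("radii must be >= 1")
        super().__init__(Z, member_specs, in_features, rng)
        self.radii = tuple(radii)
        Zd = _dense(Z)
        self.Z_powers = [
            Var(np.linalg.matrix_power(Zd, r), requires_grad=False) for r in radii
        ]

    def forward(self, X) -> Var:
        Xv = _as_var(X)
        out = None
        for Zr, m in zip(self.Z_powers, self.members):
            y = member_forward(Zr, Xv, m)
            out = y if out is None else ad.add(out, y)
        return out


def ngcn_forward(Z, X, radii, members):
    """Sum of member outputs, member for radius r aggregating through Z^r."""
    Zd = _dense(Z)
    Xv = _as_var(X)
    out = None
    for r, m in zip(radii, members):
        y = member_forward(np.linalg.matrix_power(Zd, r), Xv, m)
        out = y if out is None else ad.add(out, y)
    return out.value if not isinstance(X, Var) else out


class AuxGCN:
    """Auxiliary pooling GCN: plain stack whose last layer has n_coarse units."""

    def __init__(self, widths, in_features, rng):
        self.W: list[Var] = []
        self.b: list[Var] = []
        fan = in_features
        for w in widths:
            self.W.append(Var(_glorot(rng, fan, w)))
            self.b.append(Var(np.zeros(w)))
            fan = w

    def parameters(self):
        return self.W + self.b

    @property
    def n_coarse(self):
        return self.W[-1].shape[1]


def diffpool_coarsen(Z, X, aux_member: AuxGCN):
    """Differentiable pooling: S = row-softmax(auxGCN(Z, X)).

    Returns ``(Z_coarse, X_coarse, S)`` with ``Z' = S^T Z S`` and
    ``X' = S^T X``; each row of S lies on the probability simplex.
    """
    Zv, Xv = _as_var(_dense(Z)), _as_var(X)
    n = Zv.shape[-1]
    if aux_member.n_coarse >= n:
        raise ValueError(f"pooling must shrink the graph: {aux_member.n_coarse} >= {n}")
    H = Xv
    for W, b in zip(aux_member.W, aux_member.b):
        H = ad.relu(ad.add(ad.matmul(ad.matmul(Zv, H), W), b))
    S = ad.row_softmax(H)
    St = ad.transpose(S)
    X_coarse = ad.matmul(St, Xv)
    Z_coarse = ad.matmul(ad.matmul(St, Zv), S)
    if isinstance(X, Var):
        return Z_coarse, X_coarse, S
    return Z_coarse.value, X_coarse.value, S.value


class DiffPoolModel:
    """GPCN-shaped baseline whose projections are DiffPool assignments.

    Mirrors a k-level GPCN: between adjacent levels an auxiliary GCN produces
    the softmaxed assignment S, coarse structure matrices follow
    ``Z' = S^T Z S``, and coarse member outputs are prolonged back with S.
    """

    def __init__(self, Z_fine, member_specs, coarse_sizes, in_features,
                 aux_widths=(16,), rng=None):
        if len(coarse_sizes) != len(member_specs) - 1:
            raise ValueError("need one coarse size per level below the finest")
        rng = rng if rng is not None else np.random.default_rng()
        self.Z = Var(_dense(Z_fine), requires_grad=False)
        self.members = [Member(s, in_features, rng) for s in member_specs]
        self.aux: list[AuxGCN] = []
        for nc in coarse_sizes:
            self.aux.append(AuxGCN(tuple(aux_widths) + (nc,), in_features, rng))
            # deeper aux nets keep consuming the (pooled) input features
        self.n_levels = len(member_specs)

    def parameters(self):
        return [p for m in self.members for p in m.parameters()] + [
            p for a in self.aux for p in a.parameters()
        ]

    def level_parameters(self, level):
        params = list(self.members[level].parameters())
        if level >= 1:
            params += self.aux[level - 1].parameters()
        return params

    def forward(self, X) -> Var:
        Xv = _as_var(X)
        out = member_forward(self.Z, Xv, self.members[0])
        Z_curr, X_curr = self.Z, Xv
        prolong = None  # product of S matrices back to the fine scale
        for i, member in enumerate(self.members[1:]):
            Z_curr, X_curr, S = diffpool_coarsen(Z_curr, X_curr, self.aux[i])
            prolong = S if prolong is None else ad.matmul(prolong, S)
            y = member_forward(Z_curr, X_curr, member)
            out = ad.add(out, ad.matmul(prolong, y))
        return out

    def predict(self, X):
        return self.forward(_as_var(np.asarray(X))).value
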