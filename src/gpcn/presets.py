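"""Named model presets for the comparison experiments.

Preset names follow the standard comparison table: single GCN, plain 2- and
3-member ensembles, 2- and 3-level (A-)GPCNs, N-GCNs with radii (1,2,4) and
(1,2,4,8,16), and the DiffPool baseline.  The GPCN presets put the widest
filters at the coarsest level (64/64/64 coarse down to 16/16/16 fine for the
3-level model), so extra capacity is cheap.  ``width_scale`` shrinks every
width proportionally for desk-scale experiments.
"""

from __future__ import annotations

import numpy as np

from .hierarchy import Hierarchy
from .models import DiffPoolModel, EnsembleModel, GPCNModel, MemberSpec, NGCNModel

__all__ = ["PRESET_NAMES", "build_preset"]

_DENSE = (256, 32, 8, 1)

PRESET_NAMES = (
    "Single GCN",
    "2-GCN Ensemble",
    "3-GCN Ensemble",
    "2-level GPCN",
    "2-level A-GPCN",
    "3-level GPCN",
    "3-level A-GPCN",
    "N-GCN radii (1,2,4)",
    "N-GCN radii (1,2,4,8,16)",
    "DiffPool",
)


def _w(widths, scale):
    return tuple(max(1, int(round(w * scale))) for w in widths)


def _spec(level, gcn, dense, scale):
    return MemberSpec(level=level, gcn_filters=_w(gcn, scale), dense_filters=_w(dense[:-1], scale) + (1,))


def build_preset(
    name: str,
    hierarchy: Hierarchy,
    in_features: int = 10,
    width_scale: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Instantiate a named model preset against a graph hierarchy."""
    rng = rng if rng is not None else np.random.default_rng()
    Z_fine = hierarchy.structure_matrices[0]
    s = width_scale
    if name == "Single GCN":
        return EnsembleModel(Z_fine, [_spec(0, (64, 64, 64), _DENSE, s)], in_features, rng)
    if name == "2-GCN Ensemble":
        return EnsembleModel(
            Z_fine,
            [_spec(0, (64, 64, 64), _DENSE, s), _spec(0, (32, 32, 32), _DENSE, s)],
            in_features, rng,
        )
    if name == "3-GCN Ensemble":
        return EnsembleModel(
            Z_fine,
            [_spec(0, (64, 64, 64), _DENSE, s), _spec(0, (32, 32, 32), _DENSE, s),
             _spec(0, (16, 16, 16), _DENSE, s)],
            in_features, rng,
        )
    if name in ("2-level GPCN", "2-level A-GPCN"):
        specs = [_spec(0, (32, 32, 32), _DENSE, s), _spec(1, (64, 64, 64), _DENSE, s)]
        return GPCNModel(hierarchy, specs, in_features, adaptive="A-" in name, rng=rng)
    if name in ("3-level GPCN", "3-level A-GPCN"):
        specs = [
            _spec(0, (16, 16, 16), _DENSE, s),
            _spec(1, (32, 32, 32), _DENSE, s),
            _spec(2, (64, 64, 64), _DENSE, s),
        ]
        return GPCNModel(hierarchy, specs, in_features, adaptive="A-" in name, rng=rng)
    if name.startswith("N-GCN"):
        radii = (1, 2, 4) if "(1,2,4)" in name.replace(" ", "") and "8" not in name else (1, 2, 4, 8, 16)
        specs = [_spec(0, (64, 64, 64), _DENSE, s) for _ in radii]
        return NGCNModel(Z_fine, radii, specs, in_features, rng)
    if name == "DiffPool":
        specs = [
            _spec(0, (16, 16, 16), _DENSE, s),
            _spec(1, (32, 32, 32), _DENSE, s),
            _spec(2, (64, 64, 64), _DENSE, s),
        ]
        sizes = [g.node_count for g in hierarchy.graphs[1:]]
        return DiffPoolModel(Z_fine, specs, sizes, in_features,
                             aux_widths=_w((16,), s), rng=rng)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
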