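"""Feature-ranking methods behind a single contract.

Every selector maps ``(dataset, config) -> FeatureRanking``; ``get_ranker``
resolves the method names used throughout the benchmark and CLI, including
the ``turf:<base>`` composition syntax for the recursive wrapper.
"""

from __future__ import annotations

from typing import Callable

from ..dataio import FeatureRanking, SimulatedDataset
from .config import SelectorConfig
from .mdr import MDRModel, mdr_rank
from .penalized import PenalizedDesign, build_interaction_design, penalized_rank
from .relief import multisurf_star_rank, turf_wrap
from .trees import gbm_rank, rf_rank

__all__ = [
    "SelectorConfig",
    "MDRModel",
    "mdr_rank",
    "multisurf_star_rank",
    "turf_wrap",
    "rf_rank",
    "gbm_rank",
    "PenalizedDesign",
    "build_interaction_design",
    "penalized_rank",
    "get_ranker",
    "METHOD_NAMES",
]

Ranker = Callable[[SimulatedDataset, SelectorConfig], FeatureRanking]

METHOD_NAMES = (
    "mdr",
    "multisurf_star",
    "turf:multisurf_star",
    "rf",
    "gbm",
    "lasso",
    "lasso_int",
    "enet",
)


def get_ranker(name: str) -> Ranker:
    """Resolve a method name to a ``(dataset, config) -> FeatureRanking``."""
    if name == "mdr":
        return lambda ds, cfg: mdr_rank(ds, collect_models=False)[0]
    if name == "multisurf_star":
        return lambda ds, cfg: multisurf_star_rank(ds)
    if name.startswith("turf:"):
        base = get_ranker(name.removeprefix("turf:"))

        def _turf(ds: SimulatedDataset, cfg: SelectorConfig) -> FeatureRanking:
            return turf_wrap(
                lambda sub: base(sub, cfg),
                ds,
                drop_fraction=cfg.turf_drop_fraction,
                min_features=cfg.turf_min_features,
                method_name=name,
            )

        return _turf
    if name == "rf":
        return rf_rank
    if name == "gbm":
        return gbm_rank
    if name in ("lasso", "lasso_int", "enet"):
        return lambda ds, cfg, mode=name: penalized_rank(ds, mode, cfg)
    raise ValueError(f"unknown ranking method {name!r}")
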