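"""Shared configuration for all feature-ranking methods.

Defaults mirror widely used settings for case/control SNP panels: forests
get 1000 trees for main-effect screens and 4500 when interactions are the
target (with 35 / 70 / 200 candidate variables per split depending on panel
width), boosting uses 800 or 15,000 shallow trees at shrinkage 0.01 with a
0.5 bag fraction, recursive Relief discards 10% of the weakest features
per pass, and penalized fits pick the regularization strength by 5-fold
stratified cross-validation with an elastic-net mixing of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["SelectorConfig"]


@dataclass(frozen=True)
class SelectorConfig:
    seed: int = 0
    # random forest
    rf_n_trees: int = 1000
    rf_mtry: int = 35
    rf_importance: str = "impurity"  # or "permutation"
    # gradient boosting
    gbm_n_trees: int = 800
    gbm_shrinkage: float = 0.01
    gbm_bag_fraction: float = 0.5
    gbm_max_depth: int = 3
    # recursive Relief wrapper
    turf_drop_fraction: float = 0.10
    turf_min_features: int = 10
    # penalized regression
    cv_folds: int = 5
    enet_alpha: float = 0.5
    n_lambdas: int = 30
    penalized_loss: str = "logistic"  # or "squared"

    def __post_init__(self) -> None:
        if self.rf_n_trees <= 0 or self.gbm_n_trees <= 0 or self.cv_folds < 2:
            raise ValueError("tree counts must be positive and cv_folds >= 2")
        for name in ("gbm_bag_fraction", "turf_drop_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.enet_alpha <= 1:
            raise ValueError("enet_alpha must be in [0, 1]")
        if self.rf_importance not in ("impurity", "permutation"):
            raise ValueError("rf_importance must be 'impurity' or 'permutation'")
        if self.penalized_loss not in ("logistic", "squared"):
            raise ValueError("penalized_loss must be 'logistic' or 'squared'")

    @classmethod
    def preset(
        cls, kind: str = "main", n_snps: int = 100, seed: int = 0, **overrides
    ) -> "SelectorConfig":
        """Named presets: ``main`` (main-effect screen) or ``interaction``."""
        if kind == "main":
            cfg = cls(seed=seed, rf_n_trees=1000, rf_mtry=35, gbm_n_trees=800)
        elif kind == "interaction":
            cfg = cls(
                seed=seed,
                rf_n_trees=4500,
                rf_mtry=70 if n_snps <= 100 else 200,
                gbm_n_trees=15_000,
            )
        else:
            raise ValueError(f"unknown preset {kind!r}")
        return replace(cfg, **overrides) if overrides else cfg
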