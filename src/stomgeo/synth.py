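"""Synthetic stomatal-trait generator.

Emulates the statistical structure the geometric-constraint analysis
assumes, so every stage of the pipeline can be exercised without the
compiled literature dataset:

* per-group log10-normal stomatal size (pteridophytes and gymnosperms
  large, angiosperms small);
* stomatal index increasing with stomatal size, linear in logs,
  lg SI = si_intercept + si_slope * lg SS + noise (the observed positive
  SI-SS coupling);
* epidermal cell size proportional to stomatal size, ES = a_true * SS,
  up to multiplicative noise;
* stomatal density from the geometric model SD = 10^6/(SS * c(SI, a_true)),
  up to multiplicative noise.

All noise is multiplicative log10-normal, matching the log-scale
analyses; multipliers are mean-one (the 10^N(0, s^2) draw is divided by
its expectation exp((s ln 10)^2 / 2)) so that proportionality relations
like E[ES | SS] = a_true * SS hold on the raw scale as well and the
ratio estimators are consistent.  Stomatal length and width are back-
derived from SS with the 0.36 width ratio, so the SL-based and SS-based
analyses are mutually consistent.  Generation is fully reproducible from
the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .phylocomp import Phylogeny, generate_tree
from .traitio import StomatalRecord, TraitTable

__all__ = ["SynthConfig", "generate_traits", "generate_study_preset"]

_DEFAULT_N = {
    "pteridophyte": 40,
    "gymnosperm": 40,
    "angiosperm:magnoliid": 40,
    "angiosperm:dicot": 100,
    "angiosperm:monocot": 60,
    "angiosperm:other": 20,
}

# lg SS (um^2): ferns/gymnosperms have large stomata (~800-1250 um^2),
# angiosperms small (~200-300 um^2)
_DEFAULT_SS_MEAN = {
    "pteridophyte": 3.1,
    "gymnosperm": 2.9,
    "angiosperm:magnoliid": 2.5,
    "angiosperm:dicot": 2.3,
    "angiosperm:monocot": 2.4,
    "angiosperm:other": 2.4,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic trait generator.

    Group keys are either a major group name or 'angiosperm:<subgroup>'.
    Defaults give a 300-species table whose group structure, trait ranges
    and couplings mirror the regimes the analysis targets.
    """

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N)
    )
    ss_log10_mean: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SS_MEAN)
    )
    ss_log10_sd: float = 0.25
    si_intercept: float = 1.0  # lg SI at lg SS = 0
    si_slope: float = 0.05  # weak positive SI-SS coupling
    si_noise_sd: float = 0.05  # lg-scale
    a_true: float = 1.06
    es_noise_sd: float = 0.05  # lg-scale
    sd_noise_sd: float = 0.10  # lg-scale
    width_ratio: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group or all(v == 0 for v in self.n_per_group.values()):
            raise ValueError("n_per_group must request at least one record")
        if any(v < 0 for v in self.n_per_group.values()):
            raise ValueError("counts must be >= 0")
        for name in ("si_noise_sd", "es_noise_sd", "sd_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.a_true <= 0:
            raise ValueError("a_true must be positive")


def _mean_one_multiplier(rng, sd_log10: float, size: int) -> np.ndarray:
    """Multiplicative log10-normal noise with unit mean."""
    if sd_log10 == 0:
        return np.ones(size)
    raw = 10 ** rng.normal(0.0, sd_log10, size)
    return raw / np.exp(0.5 * (sd_log10 * np.log(10.0)) ** 2)


def _split_key(key: str) -> Tuple[str, str | None]:
    if ":" in key:
        group, subgroup = key.split(":", 1)
    else:
        group, subgroup = key, None
    return group, subgroup


def generate_traits(config: SynthConfig) -> TraitTable:
    """Draw a fully consistent synthetic :class:`TraitTable`.

    SI values are rejection-sampled into (0.5, 99.5)% so the linear-in-
    logs SI model is untouched in the bulk of the distribution while the
    0 < SI < 100 invariant always holds.
    """
    from .geometry import predict_density  # deferred: geometry imports traitio

    rng = np.random.default_rng(config.seed)
    records = []
    counter = 0
    for key, n in config.n_per_group.items():
        group, subgroup = _split_key(key)
        if n == 0:
            continue
        try:
            lg_ss_mean = config.ss_log10_mean[key]
        except KeyError:
            raise ValueError(f"no ss_log10_mean for group {key!r}") from None
        # rejection sampling: (ss, si) pairs are redrawn jointly until SI
        # lands in (0.5, 99.5)%, so SI is never truncated or clipped
        lg_ss = np.empty(n)
        si = np.empty(n)
        pending = np.arange(n)
        for _ in range(1000):
            if not pending.size:
                break
            cand_ss = rng.normal(lg_ss_mean, config.ss_log10_sd, pending.size)
            lg_si = (
                config.si_intercept
                + config.si_slope * cand_ss
                + rng.normal(0.0, config.si_noise_sd, pending.size)
            )
            cand_si = 10**lg_si
            ok = (cand_si > 0.5) & (cand_si < 99.5)
            lg_ss[pending[ok]] = cand_ss[ok]
            si[pending[ok]] = cand_si[ok]
            pending = pending[~ok]
        else:
            raise ValueError(
                f"SI model for group {key!r} almost never lands in (0.5, 99.5)%"
            )
        ss = 10**lg_ss

        es = config.a_true * ss * _mean_one_multiplier(rng, config.es_noise_sd, n)
        sd = predict_density(ss, si, config.a_true) * _mean_one_multiplier(
            rng, config.sd_noise_sd, n
        )
        sl = np.sqrt(ss / ((np.pi / 2.0) * config.width_ratio))
        sw = config.width_ratio * sl
        for i in range(n):
            counter += 1
            records.append(
                StomatalRecord(
                    species=f"{group[:4]}_{subgroup[:4] if subgroup else 'spp'}_{counter:04d}",
                    group=group,
                    subgroup=subgroup,
                    sd=float(sd[i]),
                    sl=float(sl[i]),
                    sw=float(sw[i]),
                    ss=float(ss[i]),
                    es=float(es[i]),
                    si=float(si[i]),
                    derived_flags={
                        k: "observed" for k in ("sd", "sl", "sw", "ss", "es", "si")
                    },
                )
            )
    for rec in records:
        rec.validate()
    return TraitTable(
        records=records, source_label=f"synthetic(seed={config.seed})"
    )


def generate_study_preset(seed: int = 0) -> Tuple[TraitTable, Phylogeny]:
    """Default preset: a ~300-species table plus a matching random tree.

    The tree is a pure-birth tree over exactly the table's species (tips
    relabeled to species names), so every comparative analysis can run
    end-to-end on the pair.
    """
    table = generate_traits(SynthConfig(seed=seed))
    phylo = generate_tree(n_tips=len(table), seed=seed + 1)
    # species are placed on tips in shuffled order: trait variation is
    # unrelated to the tree, the regime the comparative checks expect
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(len(table))
    for leaf, idx in zip(phylo.tree.leaf_node_iter(), order):
        leaf.taxon.label = table.records[idx].species
    phylo.source_label = f"synthetic-yule(seed={seed + 1})"
    return table, phylo
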