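"""Expression normalization, GPR evaluation and bound rescaling.

The integration step builds sample-specific models by multiplying each
reaction's flux bounds by ``gamma * reaction_expression(i)``, where
``reaction_expression(i)`` is the normalized expression of the genes encoding
reaction *i*, combined through its GPR rule::

    lb(i) <- lb(i) * gamma * reaction_expression(i)
    ub(i) <- ub(i) * gamma * reaction_expression(i)

Expression values are normalized so that control samples average 1 per gene,
which makes a control model approximate the unconstrained baseline (scaled by
gamma) and makes treated-vs-control fold changes directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import GprRule, MetabolicModel, ModelValidationError

__all__ = [
    "ExpressionProfile",
    "ReactionExpressionMap",
    "IntegrationConfig",
    "normalize_expression",
    "evaluate_gpr",
    "map_expression_to_reactions",
    "apply_expression_bounds",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_sheet",
]

CONDITIONS = ("control", "treated")


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-sample normalized gene abundances (control mean ~ 1)."""

    sample_id: str
    condition: str
    values: Mapping[str, float]
    flagged_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        for g, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"sample {self.sample_id!r}: gene {g!r} value {v} invalid")
        object.__setattr__(self, "values", dict(self.values))


@dataclass(frozen=True)
class ReactionExpressionMap:
    """Reaction-level expression values and their provenance.

    provenance[rid] is ``"gpr-evaluated"`` when a GPR was evaluated and
    ``"no-gpr-neutral"`` when the reaction has no gene association and got
    the neutral value 1.
    """

    values: Mapping[str, float]
    provenance: Mapping[str, str]

    def __post_init__(self):
        for rid, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"reaction {rid!r}: expression value {v} invalid")
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "provenance", dict(self.provenance))


_AND_OPS = {"min": min, "mean": lambda xs: float(np.mean(xs))}
_OR_OPS = {"max": max, "sum": lambda xs: float(np.sum(xs))}


@dataclass(frozen=True)
class IntegrationConfig:
    """Hyperparameters of the bound-rescaling step.

    gamma scales all bounds multiplicatively (default 2).  AND combines
    subunits of a complex (default min: the scarcest subunit limits), OR
    combines isoenzymes (default max: the best-expressed one carries flux;
    ``sum`` pools isoenzyme capacity).  Genes absent from a profile evaluate
    to ``missing_gene_value`` (default 1, i.e. neutral) so that incomplete
    annotation never silently blocks a reaction.  ``cap_factor`` optionally
    clips gamma*expression so bounds can only tighten, never widen.
    """

    gamma: float = 2.0
    and_operator: str = "min"
    or_operator: str = "max"
    missing_gene_value: float = 1.0
    cap_factor: float | None = None
    exempt_objective: bool = False

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.and_operator not in _AND_OPS:
            raise ValueError(f"and_operator must be one of {sorted(_AND_OPS)}")
        if self.or_operator not in _OR_OPS:
            raise ValueError(f"or_operator must be one of {sorted(_OR_OPS)}")
        if self.cap_factor is not None and self.cap_factor <= 0:
            raise ValueError("cap_factor must be positive when set")


def normalize_expression(
    counts: pd.DataFrame, conditions: Mapping[str, str]
) -> list[ExpressionProfile]:
    """Normalize a gene x sample raw-count table into per-sample profiles.

    Each sample is library-size scaled (to the mean library size), then each
    gene is divided by its mean across *control* samples, so control genes
    average 1.  Genes whose control mean is zero get value 0 and are flagged.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    unknown = set(counts.columns) - set(conditions)
    if unknown:
        raise ValueError(f"samples without condition labels: {sorted(unknown)}")
    controls = [s for s in counts.columns if conditions[s] == "control"]
    if not controls:
        raise ValueError("at least one control sample is required")
    libsize = counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        raise ValueError(f"empty samples: {list(libsize.index[libsize == 0])}")
    scaled = counts / libsize * libsize.mean()
    control_mean = scaled[controls].mean(axis=1)
    flagged = frozenset(control_mean.index[control_mean == 0])
    denom = control_mean.replace(0, np.nan)
    norm = scaled.div(denom, axis=0).fillna(0.0)
    return [
        ExpressionProfile(sample_id=s, condition=conditions[s],
                          values=norm[s].to_dict(), flagged_genes=flagged)
        for s in counts.columns
    ]


class _Lookup:
    def __init__(self, profile: ExpressionProfile, config: IntegrationConfig):
        self._values = profile.values
        self._missing = config.missing_gene_value
        self.and_op = _AND_OPS[config.and_operator]
        self.or_op = _OR_OPS[config.or_operator]

    def value(self, gene: str) -> float:
        return float(self._values.get(gene, self._missing))


def evaluate_gpr(
    rule: GprRule, profile: ExpressionProfile, config: IntegrationConfig | None = None
) -> float:
    """Numerically evaluate a GPR tree against one expression profile."""
    config = config or IntegrationConfig()
    return float(rule.evaluate(_Lookup(profile, config)))


def map_expression_to_reactions(
    model: MetabolicModel, profile: ExpressionProfile,
    config: IntegrationConfig | None = None,
) -> ReactionExpressionMap:
    """GPR-evaluate expression for every reaction; GPR-less reactions get 1."""
    config = config or IntegrationConfig()
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for r in model.reactions:
        if r.gpr is None:
            values[r.id] = 1.0
            provenance[r.id] = "no-gpr-neutral"
        else:
            values[r.id] = evaluate_gpr(r.gpr, profile, config)
            provenance[r.id] = "gpr-evaluated"
    return ReactionExpressionMap(values, provenance)


def apply_expression_bounds(
    model: MetabolicModel, rmap: ReactionExpressionMap,
    config: IntegrationConfig | None = None,
) -> MetabolicModel:
    """Rescale every reaction's bounds by ``gamma * reaction_expression``.

    The factor is non-negative, so bound signs are preserved and lb <= ub is
    maintained; expression 0 blocks a reaction entirely.  With ``cap_factor``
    set the factor is clipped to [0, cap_factor].
    """
    config = config or IntegrationConfig()
    missing = set(model.reaction_ids) - set(rmap.values)
    if missing:
        raise ValueError(f"expression map does not cover reactions: {sorted(missing)}")
    bounds: dict[str, tuple[float, float]] = {}
    for r in model.reactions:
        if config.exempt_objective and r.id == model.objective_reaction_id:
            continue
        f = config.gamma * rmap.values[r.id]
        if not np.isfinite(f):
            raise ValueError(f"reaction {r.id!r}: non-finite scaling factor")
        if config.cap_factor is not None:
            f = min(f, config.cap_factor)
        bounds[r.id] = (r.lb * f, r.ub * f)
    return model.with_bounds(bounds)


# ---------------------------------------------------------------------------
# TSV I/O: gene_id column plus one column per sample; a sample sheet maps
# sample -> condition.
# ---------------------------------------------------------------------------


def write_expression_tsv(profiles: Sequence[ExpressionProfile], values_path, samples_path) -> None:
    genes = sorted(set().union(*(set(p.values) for p in profiles)))
    table = pd.DataFrame(
        {p.sample_id: [p.values.get(g, np.nan) for g in genes] for p in profiles},
        index=pd.Index(genes, name="gene_id"),
    )
    table.to_csv(values_path, sep="\t")
    sheet = pd.DataFrame(
        {"sample_id": [p.sample_id for p in profiles],
         "condition": [p.condition for p in profiles]}
    )
    sheet.to_csv(samples_path, sep="\t", index=False)


def read_sample_sheet(path) -> dict[str, str]:
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample_id", "condition"} <= set(sheet.columns):
        raise ValueError(f"{path}: sample sheet needs columns sample_id, condition")
    return dict(zip(sheet["sample_id"].astype(str), sheet["condition"].astype(str)))


def read_expression_tsv(values_path, samples_path, raw_counts: bool = False
                        ) -> list[ExpressionProfile]:
    """Read profiles from TSV.  With ``raw_counts`` the table is normalized
    (library size + control-mean anchoring) instead of being used as-is."""
    table = pd.read_csv(values_path, sep="\t", index_col=0)
    conditions = read_sample_sheet(samples_path)
    missing = set(table.columns) - set(conditions)
    if missing:
        raise ValueError(f"{values_path}: samples missing from sample sheet: {sorted(missing)}")
    if raw_counts:
        return normalize_expression(table, conditions)
    return [
        ExpressionProfile(sample_id=s, condition=conditions[s], values=table[s].to_dict())
        for s in table.columns
    ]
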