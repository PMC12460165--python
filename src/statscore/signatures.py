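"""STAT-driven gene sets and their cross-STAT-exclusive subsets.

From the per-cytokine differentially regulated gene sets, each STAT's
"driven" set is defined as:

* STAT1 — the IFNa-driven genes;
* STAT6 — the IL-4-driven genes;
* STAT3 — the intersection of the IL-10- and IL-21-driven genes;
* STAT5 — the intersection of the IL-2- and IL-7-driven genes.

Intersections are taken by gene id; under the default ``concordant`` sign
mode a gene whose direction disagrees between the two cytokines is dropped
(and logged), since an induced-by-one / repressed-by-the-other gene cannot
represent a shared STAT program. A STAT's *exclusive* set is its driven
genes minus the union of every other STAT's driven genes — the gene
universe over which samples are scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10
SIGN_MODES = ("concordant", "id-only")


@dataclass
class SignatureSet:
    """Driven and exclusive gene sets for one STAT.

    ``driven`` maps gene -> sign (+1/-1); ``exclusive`` is a subset of the
    driven gene ids; ``reference_conditions`` are the cytokine conditions
    whose samples serve as the reference panel when scoring this STAT.
    """

    stat: str
    driven: dict[str, int]
    exclusive: set[str]
    reference_conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        extra = self.exclusive - set(self.driven)
        if extra:
            raise ValidationError(
                f"{self.stat}: exclusive genes not in driven set: {sorted(extra)[:5]}"
            )


def intersect_signed(
    sets: list[dict[str, int]], sign_mode: str = "concordant"
) -> tuple[dict[str, int], list[str]]:
    """Intersect signed gene sets by id; returns (result, discordant gene ids).

    ``concordant`` drops genes whose signs disagree across the inputs;
    ``id-only`` keeps them with the sign from the first set.
    """
    if sign_mode not in SIGN_MODES:
        raise ConfigError(f"unknown sign_mode {sign_mode!r}; choose from {SIGN_MODES}")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    result, discordant = {}, []
    for g in sorted(common):
        signs = {s[g] for s in sets}
        if len(signs) > 1:
            discordant.append(g)
            if sign_mode == "id-only":
                result[g] = sets[0][g]
        else:
            result[g] = sets[0][g]
    return result, discordant


def build_driven_sets(
    de_results: dict[str, dict[str, int]],
    condition_stats: dict[str, str],
    sign_mode: str = "concordant",
) -> dict[str, dict[str, int]]:
    """Combine per-cytokine DE sets into per-STAT driven sets.

    ``de_results`` maps reference condition -> signed gene set;
    ``condition_stats`` maps each reference condition to its STAT. A STAT
    with a single reference cytokine inherits that set unchanged; a STAT
    with several takes their intersection.
    """
    by_stat: dict[str, list[str]] = {}
    for cond, stat in condition_stats.items():
        by_stat.setdefault(stat, []).append(cond)
    missing = [c for conds in by_stat.values() for c in conds if c not in de_results]
    if missing:
        raise ConfigError(f"missing DE results for reference conditions: {missing}")
    driven: dict[str, dict[str, int]] = {}
    for stat, conds in sorted(by_stat.items()):
        if len(conds) == 1:
            driven[stat] = dict(de_results[conds[0]])
        else:
            merged, discordant = intersect_signed(
                [de_results[c] for c in conds], sign_mode=sign_mode
            )
            if discordant:
                logger.info(
                    "%s: %d gene(s) with discordant direction between %s dropped"
                    if sign_mode == "concordant"
                    else "%s: %d gene(s) with discordant direction between %s kept",
                    stat,
                    len(discordant),
                    "/".join(conds),
                )
            driven[stat] = merged
    return driven


def exclusive_set(stat: str, driven: dict[str, dict[str, int]]) -> set[str]:
    """Genes driven by ``stat`` but by no other STAT."""
    if stat not in driven:
        raise ConfigError(f"unknown STAT {stat!r}; have {sorted(driven)}")
    others: set[str] = set()
    for other, genes in driven.items():
        if other != stat:
            others |= set(genes)
    return set(driven[stat]) - others


def build_signatures(
    de_results: dict[str, dict[str, int]],
    samples: pd.DataFrame,
    sign_mode: str = "concordant",
    min_size: int = DEFAULT_MIN_SIZE,
) -> dict[str, SignatureSet]:
    """Full signature construction from DE results and the sample sheet.

    Reference conditions and their STATs are taken from the sample sheet's
    ``role`` and ``reference_stat`` columns.
    """
    ref = samples[samples["role"] == "reference"]
    condition_stats = (
        ref.drop_duplicates("condition").set_index("condition")["reference_stat"].to_dict()
    )
    if not condition_stats:
        raise ConfigError("sample sheet declares no reference conditions")
    driven = build_driven_sets(de_results, condition_stats, sign_mode=sign_mode)
    out: dict[str, SignatureSet] = {}
    for stat in sorted(driven):
        excl = exclusive_set(stat, driven)
        conds = sorted(c for c, s in condition_stats.items() if s == stat)
        out[stat] = SignatureSet(
            stat=stat,
            driven=driven[stat],
            exclusive=excl,
            reference_conditions=conds,
        )
        if len(excl) < min_size:
            logger.warning(
                "%s: exclusive set has %d gene(s), below min_size=%d; "
                "scores will be reported missing",
                stat,
                len(excl),
                min_size,
            )
    return out


def validate_signatures(
    sets: dict[str, SignatureSet], min_size: int = DEFAULT_MIN_SIZE
) -> list[dict]:
    """Flag exclusive sets smaller than ``min_size``.

    Returns a list of {stat, n_exclusive, min_size} records; empty when all
    sets are large enough. Scoring treats flagged STATs as missing.
    """
    report = []
    for stat in sorted(sets):
        n = len(sets[stat].exclusive)
        if n < min_size:
            report.append({"stat": stat, "n_exclusive": n, "min_size": min_size})
    return report


def signatures_to_frames(
    sets: dict[str, SignatureSet],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Tabular form: one per-STAT gene table plus a summary table."""
    per_stat = {}
    summary_rows = []
    for stat in sorted(sets):
        sig = sets[stat]
        genes = sorted(sig.driven)
        per_stat[stat] = pd.DataFrame(
            {
                "gene": genes,
                "sign": [sig.driven[g] for g in genes],
                "in_exclusive": [g in sig.exclusive for g in genes],
            }
        )
        summary_rows.append(
            {
                "stat": stat,
                "n_driven": len(sig.driven),
                "n_exclusive": len(sig.exclusive),
                "reference_conditions": ",".join(sig.reference_conditions),
            }
        )
    return per_stat, pd.DataFrame(summary_rows)


def signatures_from_frames(
    per_stat: dict[str, pd.DataFrame], summary: pd.DataFrame
) -> dict[str, SignatureSet]:
    """Inverse of :func:`signatures_to_frames`."""
    out = {}
    ref_map = dict(zip(summary["stat"], summary["reference_conditions"].fillna("")))
    for stat, df in per_stat.items():
        driven = dict(zip(df["gene"], df["sign"].astype(int)))
        exclusive = set(df.loc[df["in_exclusive"].astype(bool), "gene"])
        conds = [c for c in str(ref_map.get(stat, "")).split(",") if c]
        out[stat] = SignatureSet(stat, driven, exclusive, conds)
    return out
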