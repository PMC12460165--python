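"""Synthetic bulk RNA-seq generator for cytokine-stimulation experiments.

The generator emulates a short (6 h) stimulation design on engineered T
cells: a single unstimulated-equivalent control condition (receptor with no
intracellular domain, "no_ICD"), six reference cytokine conditions that each
activate a characteristic STAT program at full strength (IFNa -> STAT1;
IL-10 and IL-21 -> STAT3; IL-2 and IL-7 -> STAT5; IL-4 -> STAT6), and an
arbitrary number of chimeric-receptor query conditions whose responses are
attenuated versions of the native programs (partial agonism, parameterised
by an activation factor alpha in [0, 1] per STAT).

Counts are negative-binomial with variance mu + phi * mu^2 around a
multiplicative mean model:

    mu_gs = baseline_g * 2 ** (sum_k sign_gk * alpha_ck * effect_log2fc) * depth_s

where the sum runs over STAT programs containing gene g, plus any private
off-target program of the sample's condition. Ground truth (program
membership with signs, per-condition activations, baselines, gene lengths)
is returned alongside the counts so recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigError, ParameterError

STATS = ("STAT1", "STAT3", "STAT5", "STAT6")

#: canonical reference cytokine -> STAT mapping of the study design
REFERENCE_CYTOKINES = {
    "IFNa": "STAT1",
    "IL10": "STAT3",
    "IL21": "STAT3",
    "IL2": "STAT5",
    "IL7": "STAT5",
    "IL4": "STAT6",
}

CONTROL_CONDITION = "no_ICD"


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition.

    ``activation`` maps STAT id -> alpha in [0, 1], the attenuation factor
    scaling the full-strength log2 fold change of that STAT's program.
    Reference conditions carry the STAT whose scoring panel they belong to.
    """

    name: str
    role: str  # control | reference | query
    activation: dict[str, float] = field(default_factory=dict)
    reference_stat: str | None = None

    def validate(self, known_stats) -> None:
        if self.role not in io.ROLES:
            raise ConfigError(f"condition {self.name!r}: unknown role {self.role!r}")
        for stat, alpha in self.activation.items():
            if stat not in known_stats:
                raise ConfigError(
                    f"condition {self.name!r}: activation for undeclared "
                    f"program {stat!r}"
                )
            if not 0.0 <= alpha <= 1.0:
                raise ConfigError(
                    f"condition {self.name!r}: activation {alpha} outside [0, 1]"
                )
        if self.role == "control" and any(a != 0 for a in self.activation.values()):
            raise ConfigError(f"control condition {self.name!r} must be inactive")
        if self.role == "reference":
            if self.reference_stat not in known_stats:
                raise ConfigError(
                    f"reference condition {self.name!r} needs a reference_stat "
                    f"among {sorted(known_stats)}"
                )
        elif self.reference_stat is not None:
            raise ConfigError(
                f"condition {self.name!r}: reference_stat only allowed for "
                "role=reference"
            )


def default_conditions() -> list[ConditionSpec]:
    """Control plus the six canonical reference cytokine conditions."""
    conds = [ConditionSpec(CONTROL_CONDITION, "control")]
    for cyt, stat in REFERENCE_CYTOKINES.items():
        conds.append(
            ConditionSpec(cyt, "reference", activation={stat: 1.0}, reference_stat=stat)
        )
    return conds


def attenuation_series(stat: str, alphas, prefix: str = "chimera") -> list[ConditionSpec]:
    """Query conditions activating one STAT at each alpha in ``alphas``."""
    return [
        ConditionSpec(
            f"{prefix}_{stat}_a{round(a * 100):03d}", "query", activation={stat: float(a)}
        )
        for a in alphas
    ]


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated experiment; deterministic given ``seed``."""

    n_genes: int = 2000
    program_sizes: dict[str, int] = field(
        default_factory=lambda: {s: 150 for s in STATS}
    )
    overlap_fraction: float = 0.0
    frac_repressed: float = 0.3
    effect_log2fc: float = 2.0
    dispersion: float = 0.1
    baseline_log2_mean_sd: tuple[float, float] = (6.0, 2.0)
    library_size_range: tuple[float, float] = (0.7, 1.3)
    n_replicates: int = 3
    conditions: tuple[ConditionSpec, ...] = field(
        default_factory=lambda: tuple(default_conditions())
    )
    offtarget_fraction: float = 0.1
    gene_length_range: tuple[int, int] = (500, 10_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if any(s <= 0 for s in self.program_sizes.values()):
            raise ConfigError("program sizes must be positive")
        if sum(self.program_sizes.values()) > self.n_genes:
            raise ConfigError(
                f"program sizes sum to {sum(self.program_sizes.values())} "
                f"> n_genes = {self.n_genes}"
            )
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigError("overlap_fraction must be in [0, 1)")
        if not 0.0 <= self.frac_repressed <= 1.0:
            raise ConfigError("frac_repressed must be in [0, 1]")
        if self.effect_log2fc <= 0:
            raise ConfigError("effect_log2fc must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if not 0.0 <= self.offtarget_fraction < 1.0:
            raise ConfigError("offtarget_fraction must be in [0, 1)")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("library_size_range must be positive and ordered")
        glo, ghi = self.gene_length_range
        if glo <= 0 or ghi < glo:
            raise ConfigError("gene_length_range must be positive and ordered")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ConfigError("condition names must be unique")
        n_control = sum(c.role == "control" for c in self.conditions)
        if n_control != 1:
            raise ConfigError(f"exactly one control condition required, got {n_control}")
        for c in self.conditions:
            c.validate(self.program_sizes.keys())

    def with_conditions(self, extra: list[ConditionSpec]) -> "SimConfig":
        return replace(self, conditions=tuple(self.conditions) + tuple(extra))


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``program_members`` maps STAT id -> {gene: sign} with sign +1 (induced)
    or -1 (repressed) at full activation; ``offtarget_members`` maps a
    reference condition -> its private {gene: sign} program.
    """

    program_members: dict[str, dict[str, int]]
    offtarget_members: dict[str, dict[str, int]]
    condition_activation: dict[str, dict[str, float]]
    baseline_means: dict[str, float]
    gene_lengths: dict[str, int]

    def to_json_obj(self) -> dict:
        return {
            "program_members": self.program_members,
            "offtarget_members": self.offtarget_members,
            "condition_activation": self.condition_activation,
            "baseline_means": self.baseline_means,
            "gene_lengths": self.gene_lengths,
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "SimTruth":
        return cls(
            program_members={
                k: {g: int(s) for g, s in v.items()}
                for k, v in obj["program_members"].items()
            },
            offtarget_members={
                k: {g: int(s) for g, s in v.items()}
                for k, v in obj["offtarget_members"].items()
            },
            condition_activation={
                k: {s: float(a) for s, a in v.items()}
                for k, v in obj["condition_activation"].items()
            },
            baseline_means={g: float(m) for g, m in obj["baseline_means"].items()},
            gene_lengths={g: int(l) for g, l in obj["gene_lengths"].items()},
        )


def nb_sample(mean, dispersion, rng) -> np.ndarray:
    """Draw negative-binomial counts with variance ``mean + dispersion * mean**2``.

    ``dispersion = 0`` degenerates to Poisson. ``mean`` may be scalar or array.
    """
    mean = np.asarray(mean, dtype=float)
    if (mean <= 0).any():
        raise ParameterError("nb_sample: mean must be positive")
    if dispersion < 0:
        raise ParameterError("nb_sample: dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # NB shape: var = mu + mu^2 / size
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _assign_programs(config: SimConfig, rng) -> tuple[dict, dict, np.ndarray]:
    """Assign genes to STAT programs with signs, plus per-condition off-targets.

    Programs are laid out disjointly except that, for overlap_fraction > 0,
    each program after the first shares its first ceil(f * size) genes with
    the previous program (one partner program each).
    """
    genes = np.array([f"gene{i:05d}" for i in range(config.n_genes)])
    stats = sorted(config.program_sizes)
    sign_of = {}  # gene -> sign, shared across programs for consistency

    def draw_signs(members):
        n_rep = round(config.frac_repressed * len(members))
        repressed = set(rng.choice(len(members), size=n_rep, replace=False))
        for i, g in enumerate(members):
            sign_of.setdefault(g, -1 if i in repressed else +1)

    program_members: dict[str, dict[str, int]] = {}
    cursor = 0
    prev_members: list[str] = []
    for idx, stat in enumerate(stats):
        size = config.program_sizes[stat]
        n_shared = 0
        members: list[str] = []
        if idx > 0 and config.overlap_fraction > 0:
            n_shared = min(math.ceil(config.overlap_fraction * size), len(prev_members))
            members.extend(prev_members[-n_shared:])
        n_new = size - n_shared
        members.extend(genes[cursor : cursor + n_new])
        cursor += n_new
        draw_signs(members)
        program_members[stat] = {g: sign_of[g] for g in members}
        prev_members = members

    # private off-target programs: one per reference condition of a STAT that
    # has two or more reference cytokines (so the intersection step matters)
    stat_refcount: dict[str, int] = {}
    for c in config.conditions:
        if c.role == "reference":
            stat_refcount[c.reference_stat] = stat_refcount.get(c.reference_stat, 0) + 1
    offtarget_members: dict[str, dict[str, int]] = {}
    for c in config.conditions:
        if c.role != "reference" or stat_refcount.get(c.reference_stat, 0) < 2:
            continue
        n_off = math.ceil(
            config.offtarget_fraction * config.program_sizes[c.reference_stat]
        )
        if cursor + n_off > config.n_genes:
            raise ConfigError("not enough genes for off-target programs")
        members = list(genes[cursor : cursor + n_off])
        cursor += n_off
        draw_signs(members)
        offtarget_members[c.name] = {g: sign_of[g] for g in members}
    return program_members, offtarget_members, genes


def simulate_experiment(
    config: SimConfig,
) -> tuple[io.CountMatrix, pd.Series, SimTruth]:
    """Simulate counts, gene lengths and ground truth for ``config``.

    Returns a :class:`~statscore.io.CountMatrix`, a gene-length Series
    (bases) and a :class:`SimTruth`. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    baseline = 2.0 ** rng.normal(*config.baseline_log2_mean_sd, size=config.n_genes)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    program_members, offtarget_members, genes = _assign_programs(config, rng)
    gene_pos = {g: i for i, g in enumerate(genes)}

    sample_ids, sample_cond = [], []
    for c in config.conditions:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{c.name}_r{r}")
            sample_cond.append(c)
    depth = rng.uniform(*config.library_size_range, size=len(sample_ids))

    # per-condition log2 effect vector
    cond_effect: dict[str, np.ndarray] = {}
    for c in config.conditions:
        eff = np.zeros(config.n_genes)
        for stat, alpha in c.activation.items():
            for g, sign in program_members[stat].items():
                eff[gene_pos[g]] += sign * alpha * config.effect_log2fc
        for g, sign in offtarget_members.get(c.name, {}).items():
            eff[gene_pos[g]] += sign * config.effect_log2fc
        cond_effect[c.name] = eff

    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    for j, (sid, c) in enumerate(zip(sample_ids, sample_cond)):
        mu = baseline * 2.0 ** cond_effect[c.name] * depth[j]
        counts[:, j] = nb_sample(mu, config.dispersion, rng)

    counts_df = pd.DataFrame(
        counts, index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    samples_df = pd.DataFrame(
        {
            "condition": [c.name for c in sample_cond],
            "role": [c.role for c in sample_cond],
            "reference_stat": [c.reference_stat for c in sample_cond],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    matrix = io.CountMatrix(counts_df, samples_df)
    lengths_s = pd.Series(lengths, index=counts_df.index, name="length")
    truth = SimTruth(
        program_members=program_members,
        offtarget_members=offtarget_members,
        condition_activation={
            c.name: {s: float(a) for s, a in sorted(c.activation.items())}
            for c in config.conditions
        },
        baseline_means={g: float(b) for g, b in zip(genes, baseline)},
        gene_lengths={g: int(l) for g, l in zip(genes, lengths)},
    )
    return matrix, lengths_s, truth


def write_fixture(
    matrix: io.CountMatrix,
    lengths: pd.Series,
    truth: SimTruth | None,
    directory: Path,
) -> dict[str, Path]:
    """Write counts/lengths/samples TSVs (and truth.json if given) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "lengths": directory / "lengths.tsv",
        "samples": directory / "samples.tsv",
    }
    io.write_counts(matrix.counts, paths["counts"])
    io.write_lengths(lengths, paths["lengths"])
    io.write_sample_sheet(matrix.samples, paths["samples"])
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        io.write_json(truth.to_json_obj(), paths["truth"])
    return paths


def read_fixture(directory: Path) -> tuple[io.CountMatrix, pd.Series, SimTruth | None]:
    """Read a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    matrix = io.read_count_matrix(directory / "counts.tsv", directory / "samples.tsv")
    lengths = io.read_lengths(directory / "lengths.tsv")
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        truth = SimTruth.from_json_obj(io.read_json(truth_path))
    return matrix, lengths, truth
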