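"""Genotype-lattice evolutionary landscape and the bootstrap epistasis test.

Between two receptor alleles differing at n amino-acid sites there are 2^n
intermediate genotypes (the vertices of a hypercube) and n! monotone
mutational paths that add one substitution per step. Each genotype is
phenotyped by the PC1 projections of its sensillum recordings. Two analyses
run on the lattice:

* **path accessibility** — every hypercube edge is tested for a significant
  *increase* in mean PC1 (a step toward the derived, C4-tuned state); edges
  passing are drawn solid, the rest dashed.

* **epistasis** — for a pair of mutation groups A and B (single+single or
  single+double), the per-sensillum "effects" of each group are its
  phenotype values minus the initial genotype's mean. Sampling one effect
  from each group at random (with replacement, 1000 draws) and summing them
  on top of the initial mean builds the distribution expected if the two
  effects combine additively; a Wilcoxon rank-sum test against the observed
  combined-genotype phenotypes, Bonferroni-corrected, flags epistasis at
  p < 0.05, with the sign from the direction of the observed departure.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from irtuning.stats_core import gated_two_sample_test
from irtuning.tables_io import ResponseMatrix
from irtuning import spike_quantification, tuning_space

logger = logging.getLogger(__name__)

WILDTYPE_LABEL = "wt"
MAX_HYPERCUBE_N = 20
MAX_PATHS_N = 8
DEFAULT_N_BOOT = 1000
MIN_N_BOOT_WARN = 100


class HypercubeSizeError(ValueError):
    """Mutation set too large to enumerate."""


class MissingGenotypeError(ValueError):
    """Response matrix lacks required genotypes."""


@dataclass(frozen=True)
class MutationSet:
    """Ordered, uniquely named substitutions (e.g. T289S, Q536K, F538L)."""

    names: tuple[str, ...]

    def __init__(self, names: Sequence[str]):
        names = tuple(names)
        if not names:
            raise ValueError("need at least one mutation")
        if len(set(names)) != len(names):
            raise ValueError("mutation names must be unique")
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class Genotype:
    """One vertex of the hypercube: a subset of the mutation set."""

    muts: MutationSet
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != self.muts.n or any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be a 0/1 vector of length n")

    @property
    def mutations(self) -> tuple[str, ...]:
        return tuple(m for m, b in zip(self.muts.names, self.bits) if b)

    @property
    def label(self) -> str:
        return ",".join(self.mutations) if any(self.bits) else WILDTYPE_LABEL

    @property
    def order(self) -> int:
        return sum(self.bits)

    def add(self, mutation: str) -> "Genotype":
        idx = self.muts.names.index(mutation)
        if self.bits[idx]:
            raise ValueError(f"{mutation} already present in {self.label}")
        bits = list(self.bits)
        bits[idx] = 1
        return Genotype(self.muts, tuple(bits))

    def union(self, other: "Genotype") -> "Genotype":
        return Genotype(self.muts, tuple(max(a, b) for a, b in zip(self.bits, other.bits)))


def genotype_from_mutations(muts: MutationSet, present: Sequence[str]) -> Genotype:
    bits = [1 if name in set(present) else 0 for name in muts.names]
    unknown = set(present) - set(muts.names)
    if unknown:
        raise ValueError(f"unknown mutations {sorted(unknown)}")
    return Genotype(muts, tuple(bits))


def enumerate_genotypes(muts: MutationSet) -> list[Genotype]:
    """All 2^n genotypes between the initial and final allele, label-sorted."""
    if muts.n > MAX_HYPERCUBE_N:
        size = 2.0 ** muts.n
        exponent = int(np.floor(np.log10(size)))
        mantissa = size / 10 ** exponent
        raise HypercubeSizeError(
            f"2^{muts.n} = {mantissa:.0f} x 10^{exponent} genotypes; enumeration is "
            f"capped at n = {MAX_HYPERCUBE_N}"
        )
    genotypes = [Genotype(muts, bits) for bits in itertools.product((0, 1), repeat=muts.n)]
    return sorted(genotypes, key=lambda g: g.label)


def enumerate_paths(muts: MutationSet) -> list[tuple[Genotype, ...]]:
    """All n! monotone paths from the empty to the full mutation set."""
    if muts.n > MAX_PATHS_N:
        raise HypercubeSizeError(f"path enumeration capped at n = {MAX_PATHS_N} ({muts.n}! paths otherwise)")
    paths = []
    start = Genotype(muts, (0,) * muts.n)
    for order in itertools.permutations(muts.names):
        chain = [start]
        for mutation in order:
            chain.append(chain[-1].add(mutation))
        paths.append(tuple(chain))
    return paths


@dataclass
class PhenotypeSample:
    """Per-sensillum scalar phenotypes (PC1 scores) of one genotype."""

    genotype: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.values = self.values[~np.isnan(self.values)]

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(self.values.std(ddof=1) / np.sqrt(self.n)) if self.n > 1 else float("nan")


@dataclass(frozen=True)
class StepResult:
    """Accessibility classification of one hypercube edge."""

    from_genotype: str
    to_genotype: str
    p_raw: float
    p_corrected: float
    direction: Literal["increase", "decrease"]
    classification: Literal["solid", "dashed"]
    test_used: str


@dataclass
class EpistasisResult:
    """Observed vs bootstrap-additive phenotype of a combined genotype."""

    pair: tuple[str, str]
    combined: str
    expected_distribution: np.ndarray
    observed: PhenotypeSample
    p_raw: float
    p_corrected: float
    epistatic: bool
    sign: Literal["negative", "positive"]

    @property
    def expected_mean(self) -> float:
        return float(self.expected_distribution.mean())


def step_test(
    a: PhenotypeSample,
    b: PhenotypeSample,
    alpha: float = 0.05,
    m: int = 1,
) -> StepResult:
    """Classify the edge a -> b: solid iff mean PC1 significantly increases.

    Uses the Shapiro-gated t/rank-sum test, two-sided, Bonferroni-corrected
    for a family of ``m`` comparisons; the direction comes from the
    difference of sample means.
    """
    if a.n < 3 or b.n < 3:
        raise ValueError(f"step test needs >=3 values per genotype ({a.genotype}: {a.n}, {b.genotype}: {b.n})")
    outcome = gated_two_sample_test(a.values, b.values, family_size=m)
    direction: Literal["increase", "decrease"] = "increase" if b.mean > a.mean else "decrease"
    solid = outcome.p_corrected < alpha and direction == "increase"
    return StepResult(
        from_genotype=a.genotype,
        to_genotype=b.genotype,
        p_raw=outcome.p_raw,
        p_corrected=outcome.p_corrected,
        direction=direction,
        classification="solid" if solid else "dashed",
        test_used=outcome.test_used,
    )


def epistasis_test(
    initial: PhenotypeSample,
    int_a: PhenotypeSample,
    int_b: PhenotypeSample,
    combined: PhenotypeSample,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
    m: int = 1,
    alpha: float = 0.05,
) -> EpistasisResult:
    """Bootstrap additivity test for the interaction of two mutation groups.

    The effect of each intermediate genotype is its phenotype values minus
    the initial genotype's mean. ``n_boot`` sums of one effect from each
    group (drawn uniformly with replacement), recentered on the initial
    mean, form the expected distribution under additivity; a two-sided
    Wilcoxon rank-sum test compares it with the observed combined-genotype
    values. Epistatic iff the Bonferroni-corrected p is below ``alpha``;
    the sign is negative when the observed mean falls short of the additive
    expectation.
    """
    for sample in (initial, int_a, int_b, combined):
        if sample.n == 0:
            raise ValueError(f"empty phenotype sample for genotype {sample.genotype!r}")
    if n_boot < MIN_N_BOOT_WARN:
        logger.warning("n_boot=%d is small; expected distribution will be noisy", n_boot)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = initial.mean
    effects_a = int_a.values - base
    effects_b = int_b.values - base
    idx_a = rng.integers(0, effects_a.size, size=n_boot)
    idx_b = rng.integers(0, effects_b.size, size=n_boot)
    expected = base + effects_a[idx_a] + effects_b[idx_b]

    res = stats.mannwhitneyu(expected, combined.values, alternative="two-sided", method="asymptotic")
    p_raw = float(res.pvalue)
    p_corrected = min(1.0, m * p_raw)
    return EpistasisResult(
        pair=(int_a.genotype, int_b.genotype),
        combined=combined.genotype,
        expected_distribution=expected,
        observed=combined,
        p_raw=p_raw,
        p_corrected=p_corrected,
        epistatic=p_corrected < alpha,
        sign="negative" if combined.mean < float(expected.mean()) else "positive",
    )


def epistasis_pairs(muts: MutationSet) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Mutation-group pairs tested for interaction: every single with every
    disjoint single or double (the combined genotype is their union)."""
    singles = [(name,) for name in muts.names]
    doubles = [tuple(pair) for pair in itertools.combinations(muts.names, 2)]
    pairs: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    seen: set[frozenset[tuple[str, ...]]] = set()
    for a in singles:
        for b in singles + doubles:
            if set(a) & set(b):
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((a, b))
    return pairs


@dataclass
class LandscapeReport:
    """Full evolutionary-landscape analysis of one response panel."""

    muts: MutationSet
    phenotypes: dict[str, PhenotypeSample]
    pca: tuning_space.PCAResult | None
    steps: list[StepResult]
    epistasis: list[EpistasisResult]
    family_size: int
    alpha: float

    def genotype_summary(self) -> pd.DataFrame:
        rows = [
            {"genotype": label, "n": s.n, "pc1_mean": s.mean, "pc1_sem": s.sem}
            for label, s in self.phenotypes.items()
        ]
        return pd.DataFrame(rows).set_index("genotype")

    def steps_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def epistasis_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group_a": r.pair[0],
                "group_b": r.pair[1],
                "combined": r.combined,
                "observed_mean": r.observed.mean,
                "expected_mean": r.expected_mean,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "epistatic": r.epistatic,
                "sign": r.sign,
            }
            for r in self.epistasis
        ]
        return pd.DataFrame(rows)

    def epistatic_pairs(self) -> list[tuple[str, str]]:
        return [r.pair for r in self.epistasis if r.epistatic]

    def to_files(self, out_dir: str | Path, prefix: str = "landscape") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": out_dir / f"{prefix}_genotypes.csv",
            "steps": out_dir / f"{prefix}_steps.csv",
            "epistasis": out_dir / f"{prefix}_epistasis.csv",
            "summary": out_dir / f"{prefix}_summary.json",
        }
        self.genotype_summary().to_csv(paths["genotypes"])
        self.steps_frame().to_csv(paths["steps"], index=False)
        self.epistasis_frame().to_csv(paths["epistasis"], index=False)
        with open(paths["summary"], "w") as fh:
            json.dump(
                {
                    "mutations": list(self.muts.names),
                    "family_size": self.family_size,
                    "alpha": self.alpha,
                    "pc1_variance_fraction": (
                        self.pca.pc1_variance_fraction if self.pca is not None else None
                    ),
                    "n_solid_steps": sum(s.classification == "solid" for s in self.steps),
                    "n_epistatic": sum(r.epistatic for r in self.epistasis),
                    "epistatic_pairs": [list(p) for p in self.epistatic_pairs()],
                },
                fh,
                indent=2,
            )
        return paths


def phenotype_samples(
    matrix: ResponseMatrix,
    muts: MutationSet,
    pca: tuning_space.PCAResult | None = None,
    phenotype: str = "pc1",
) -> tuple[dict[str, PhenotypeSample], tuning_space.PCAResult | None]:
    """Pool per-genotype scalar phenotypes from a response panel.

    ``phenotype`` selects the scalar readout:

    * ``"pc1"`` — PC1 projection of per-sensillum z-scored rows (the
      standard pipeline). Note that per-row z-scoring is a nonlinear
      normalization, so effects additive in spikes/s are not exactly
      additive on this scale.
    * ``"pc1_raw"`` — PC1 projection of the raw solvent-corrected rows;
      linear in the responses, so spikes/s additivity is preserved.
    * ``"odor:<name>"`` — the response to a single odor.
    """
    if phenotype.startswith("odor:"):
        odor = phenotype.split(":", 1)[1]
        if odor not in matrix.odors:
            raise ValueError(f"odor {odor!r} not in matrix columns {matrix.odors}")
        samples = {
            g.label: PhenotypeSample(g.label, matrix.rows_for(g.label)[odor].to_numpy())
            for g in enumerate_genotypes(muts)
        }
        return samples, None
    if phenotype == "pc1":
        source = spike_quantification.zscore_matrix(matrix)
    elif phenotype == "pc1_raw":
        source = matrix
    else:
        raise ValueError(f"unknown phenotype mode {phenotype!r}")
    if pca is None:
        pca = tuning_space.run_pca(source)
    by_label = tuning_space.project_pc1_by_label(source, pca)
    samples = {
        g.label: PhenotypeSample(g.label, by_label.get(g.label, np.empty(0)))
        for g in enumerate_genotypes(muts)
    }
    return samples, pca


def run_landscape(
    matrix: ResponseMatrix,
    muts: MutationSet,
    pca: tuning_space.PCAResult | None = None,
    alpha: float = 0.05,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    family_size: int | None = None,
    min_n: int = 3,
    phenotype: str = "pc1",
) -> LandscapeReport:
    """Full lattice analysis: per-genotype PC1, step tests, epistasis tests.

    The Bonferroni family defaults to the total number of statistical
    comparisons performed in this invocation (all step tests plus all
    epistasis tests); pass ``family_size`` to override. ``phenotype``
    selects the scalar readout (see :func:`phenotype_samples`).
    """
    samples, pca = phenotype_samples(matrix, muts, pca, phenotype=phenotype)
    genotypes = enumerate_genotypes(muts)
    short = [label for label, s in samples.items() if s.n < min_n]
    if short:
        raise MissingGenotypeError(
            f"genotypes with fewer than {min_n} phenotyped sensilla: {sorted(short)}"
        )

    edges = [
        (g, g.add(mutation))
        for g in genotypes
        for mutation in muts.names
        if mutation not in g.mutations
    ]
    pairs = epistasis_pairs(muts)
    m = family_size if family_size is not None else len(edges) + len(pairs)

    steps = [
        step_test(samples[a.label], samples[b.label], alpha=alpha, m=m) for a, b in edges
    ]

    child_seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    initial = samples[WILDTYPE_LABEL]
    epistasis: list[EpistasisResult] = []
    for (group_a, group_b), child in zip(pairs, child_seeds):
        ga = genotype_from_mutations(muts, group_a)
        gb = genotype_from_mutations(muts, group_b)
        combined = ga.union(gb)
        epistasis.append(
            epistasis_test(
                initial,
                samples[ga.label],
                samples[gb.label],
                samples[combined.label],
                n_boot=n_boot,
                seed=np.random.default_rng(child),
                m=m,
                alpha=alpha,
            )
        )

    return LandscapeReport(
        muts=muts,
        phenotypes=samples,
        pca=pca,
        steps=steps,
        epistasis=epistasis,
        family_size=m,
        alpha=alpha,
    )
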