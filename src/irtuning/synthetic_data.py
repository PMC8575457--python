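"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three kinds of raw material the analyses consume:

* Poisson spike trains with a baseline rate, an odor-evoked rate during a
  500 ms pulse arriving 200 ms after valve opening, and a finite recording
  span — exercising the window-count response estimator.
* Response panels over the full 2^n genotype hypercube: each genotype's
  expected tuning is the initial allele's baseline curve plus per-odor
  additive effects of its mutations plus optional pairwise interaction
  terms, with i.i.d. Gaussian sensillum noise and an optional fraction of
  missing cells. Panel noise is Gaussian, not Poisson: recorded responses
  are solvent-corrected differences of window counts, which are
  approximately normal; count-level realism lives in the spike generator.
* The ten-species drosophilid tree with C2/C4 tuning states at the tips,
  for the parsimony analysis.

One global seed fans out deterministically to per-component child seeds, so
each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from irtuning.landscape_epistasis import Genotype, MutationSet, enumerate_genotypes
from irtuning.phenotype_parsimony import PhenoTree, tree_from_string
from irtuning.spike_quantification import SpikeTrain
from irtuning.tables_io import ResponseMatrix

#: standard drosophilid topology for the ten species with recorded ac2 responses
FIXTURE_NEWICK = (
    "((((((Dmel,(Dsim,Dsec)),(Dyak,Dere)),Dana),Dpse),Dwil),(Dmoj,Dvir));"
)

#: tuning clusters of the ten species: acetic-acid (C2) vs butyric-acid (C4) sensors
FIXTURE_TIP_STATES = {
    "Dmel": "C2",
    "Dsim": "C2",
    "Dyak": "C2",
    "Dere": "C2",
    "Dana": "C2",
    "Dpse": "C2",
    "Dsec": "C4",
    "Dwil": "C4",
    "Dmoj": "C4",
    "Dvir": "C4",
}

#: C2-sensor tuning curve of the initial allele, spikes/s over the acid series
DEFAULT_BASELINE_TUNING = {
    "C1": 30.0,
    "C2": 90.0,
    "C3": 40.0,
    "C4": 10.0,
    "C5": 5.0,
    "C6": 2.0,
}


@dataclass
class SpikeSimConfig:
    """Inhomogeneous-Poisson spike-train generator settings (rates in Hz)."""

    baseline_rate: float = 20.0
    evoked_rate: float = 60.0
    stimulus_onset: float = 5.0
    delivery_delay: float = 0.2
    pulse_duration: float = 0.5
    recording_span: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.evoked_rate < 0:
            raise ValueError("rates must be non-negative")
        delivery = self.stimulus_onset + self.delivery_delay
        if delivery - 2.0 < 0 or delivery + self.pulse_duration > self.recording_span:
            raise ValueError("recording span must cover the baseline and stimulus windows")


def simulate_spike_train(cfg: SpikeSimConfig) -> SpikeTrain:
    """Poisson spike train: baseline rate everywhere except the odor pulse.

    The rate steps to ``evoked_rate`` during [delivery, delivery + pulse)
    where delivery = onset + delay. Segment counts are Poisson, spike times
    uniform within each segment; output times are sorted and reproducible
    for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    delivery = cfg.stimulus_onset + cfg.delivery_delay
    segments = [
        (0.0, delivery, cfg.baseline_rate),
        (delivery, delivery + cfg.pulse_duration, cfg.evoked_rate),
        (delivery + cfg.pulse_duration, cfg.recording_span, cfg.baseline_rate),
    ]
    times = []
    for start, end, rate in segments:
        span = max(0.0, end - start)
        count = rng.poisson(rate * span)
        times.append(start + span * rng.random(count))
    all_times = np.sort(np.concatenate(times))
    return SpikeTrain(
        spike_times=all_times,
        stimulus_onset=cfg.stimulus_onset,
        delivery_delay=cfg.delivery_delay,
        window=cfg.pulse_duration,
        recording_span=cfg.recording_span,
    )


@dataclass
class PanelSimConfig:
    """Hypercube response-panel generator settings.

    ``effects`` maps each mutation to its per-odor additive shift (spikes/s);
    ``interactions`` maps unordered mutation pairs to a per-odor shift added
    when both are present. Defaults model ten sensilla per genotype with
    5 spikes/s recording noise and no missing cells.
    """

    baseline_tuning: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_TUNING))
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    interactions: Mapping[frozenset, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 5.0
    n_sensilla: int = 10
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.interactions = {frozenset(k): dict(v) for k, v in self.interactions.items()}
        if self.n_sensilla < 3:
            raise ValueError("need at least 3 sensilla per genotype")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def expected_tuning(cfg: PanelSimConfig, genotype: Genotype) -> np.ndarray:
    """Noise-free expected response of a genotype over the panel's odors."""
    odors = list(cfg.baseline_tuning)
    values = np.array([cfg.baseline_tuning[o] for o in odors], dtype=float)
    present = set(genotype.mutations)
    for mutation in present:
        shifts = cfg.effects.get(mutation, {})
        values += np.array([shifts.get(o, 0.0) for o in odors])
    for pair, shifts in cfg.interactions.items():
        if pair <= present:
            values += np.array([shifts.get(o, 0.0) for o in odors])
    return values


def simulate_panel(cfg: PanelSimConfig, muts: MutationSet) -> tuple[ResponseMatrix, dict]:
    """Response panel over all 2^n genotypes, plus the ground truth used.

    Each sensillum row is the genotype's expected tuning plus i.i.d.
    Gaussian noise; cells are independently masked missing at
    ``missing_rate``. Returns the matrix and a ground-truth record with the
    programmed expected curves per genotype.
    """
    rng = np.random.default_rng(cfg.seed)
    odors = list(cfg.baseline_tuning)
    genotypes = enumerate_genotypes(muts)
    labels, rows = [], []
    truth: dict = {"odors": odors, "expected": {}, "noise_sd": cfg.noise_sd, "n_sensilla": cfg.n_sensilla}
    for genotype in genotypes:
        mu = expected_tuning(cfg, genotype)
        truth["expected"][genotype.label] = mu.tolist()
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_sensilla, len(odors)))
        block = mu[None, :] + noise
        if cfg.missing_rate > 0:
            mask = rng.random(block.shape) < cfg.missing_rate
            block = np.where(mask, np.nan, block)
        rows.append(block)
        labels.extend([genotype.label] * cfg.n_sensilla)
    data = np.vstack(rows)
    return ResponseMatrix.from_records(labels, data, odors=odors), truth


def ir75a_like_config(
    n_sensilla: int = 10,
    noise_sd: float = 5.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    interaction: Mapping[frozenset, Mapping[str, float]] | None = None,
) -> tuple[PanelSimConfig, MutationSet]:
    """Three-substitution landscape emulating the C2 -> C4 tuning switch.

    The initial allele is a C2 sensor; the three pocket substitutions each
    shift tuning toward C4 (lowering C2, raising C4/C5), so the full triple
    mutant is a C4 sensor. Additive by default; pass ``interaction`` terms
    to program epistasis.
    """
    muts = MutationSet(("T289S", "Q536K", "F538L"))
    effects = {
        "T289S": {"C2": -20.0, "C4": 15.0, "C5": 5.0},
        "Q536K": {"C2": -25.0, "C4": 20.0, "C5": 8.0},
        "F538L": {"C2": -30.0, "C4": 25.0, "C5": 10.0},
    }
    cfg = PanelSimConfig(
        effects=effects,
        interactions=dict(interaction or {}),
        noise_sd=noise_sd,
        n_sensilla=n_sensilla,
        missing_rate=missing_rate,
        seed=seed,
    )
    return cfg, muts


def fixture_tree() -> PhenoTree:
    """Ten-species drosophilid phylogeny with C2/C4 tip tuning states."""
    return tree_from_string(FIXTURE_NEWICK, FIXTURE_TIP_STATES)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from one global seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]
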