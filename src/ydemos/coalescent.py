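"""Kingman coalescent simulation under piecewise-constant demography.

The demographic model is a single deme of ``n0`` haploid gene copies at the
present with a list of historical resize events.  Looking backward in time,
when an event at time ``t`` (generations) is crossed the current size is
multiplied by the event's ``size_factor`` — the relative-size convention of
standard coalescent simulators, under which a factor below 1 is a backward
contraction (a forward expansion).  With ``k`` ancestral lineages and
current size ``N`` gene copies the coalescence rate is ``k(k-1)/(2N)`` per
generation; sizes are haploid counts so no ploidy factor enters.

Mutations are dropped under the infinite-sites model with a *fixed* budget:
exactly ``n_snps`` mutations are placed, each on a branch chosen with
probability proportional to branch length, and each defines one biallelic
SNP column carried by the tips below the branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genealogy import Genealogy
from .haplotypes import HaplotypeMatrix

__all__ = [
    "HistoricalEvent",
    "DemographicModel",
    "SimulationConfig",
    "JOMON_MODEL",
    "simulate_genealogy",
    "drop_mutations",
]


@dataclass(frozen=True)
class HistoricalEvent:
    """A backward-in-time resize: at ``time`` generations before present the
    current deme size is multiplied by ``size_factor``."""

    time: float
    size_factor: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.size_factor <= 0:
            raise ValueError("size factor must be positive")


@dataclass(frozen=True)
class DemographicModel:
    """Single-deme demography: present size plus ordered resize events."""

    n0: float
    growth_rate: float = 0.0
    events: tuple[HistoricalEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("present size must be positive")
        if self.growth_rate != 0.0:
            raise ValueError("only zero growth rate is supported")
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def epoch_sizes(self) -> list[float]:
        """Deme size in each backward epoch (present epoch first)."""
        sizes = [self.n0]
        for ev in self.events:
            sizes.append(sizes[-1] * ev.size_factor)
        return sizes

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        events = tuple(
            HistoricalEvent(float(e["time"]), float(e["size_factor"]))
            for e in d.get("events", ())
        )
        return cls(float(d["n0"]), float(d.get("growth_rate", 0.0)), events)

    def to_dict(self) -> dict:
        return {
            "n0": self.n0,
            "growth_rate": self.growth_rate,
            "events": [
                {"time": e.time, "size_factor": e.size_factor} for e in self.events
            ],
        }


#: The three-event bottleneck-and-recovery model: 10,000 gene copies at
#: present, contracting to 1,120 at 80 generations back, re-expanding to
#: 4,009.6 at 120, and dropping to 689.65 beyond 580 generations — read
#: forward in time: an ancient increase, a sharp decrease, and a rapid
#: recent recovery.
JOMON_MODEL = DemographicModel(
    n0=10_000,
    events=(
        HistoricalEvent(80, 0.112),
        HistoricalEvent(120, 3.58),
        HistoricalEvent(580, 0.172),
    ),
)


@dataclass
class SimulationConfig:
    """Replicated-simulation settings: tips per run, SNP budget, replicates."""

    sample_size: int = 200
    n_snps: int = 28_254
    n_runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_size < 2:
            raise ValueError("sample_size must be at least 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be at least 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")


def simulate_genealogy(
    model: DemographicModel, n: int, rng: np.random.Generator
) -> Genealogy:
    """Simulate one Kingman genealogy of ``n`` tips under ``model``.

    Waiting times are exponential at rate ``k(k-1)/(2N)``; crossing an event
    boundary only changes the rate (the exponential's memorylessness makes
    redrawing after the crossing exact).  Node times are in generations.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    sizes = model.epoch_sizes()
    bounds = [e.time for e in model.events] + [np.inf]
    epoch = 0
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / (2.0 * sizes[epoch])
        wait = rng.exponential(1.0 / rate)
        if t + wait > bounds[epoch]:
            t = bounds[epoch]
            epoch += 1
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = active.pop(j)
        a = active.pop(i)
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active.append(nxt)
        nxt += 1
    return Genealogy(parent, time)


def drop_mutations(
    gen: Genealogy, n_snps: int, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Place exactly ``n_snps`` infinite-sites mutations on ``gen``.

    The mutation counts per branch are a single multinomial draw with
    probabilities proportional to branch lengths; each mutation becomes one
    0/1 column, derived (1) for tips below the mutated branch.  Columns are
    ordered by branch index and assigned synthetic positions ``1..n_snps``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    lengths = gen.branch_lengths()
    total = lengths.sum()
    if total <= 0:
        raise ValueError("genealogy has zero total branch length")
    counts = rng.multinomial(n_snps, lengths / total)
    masks = gen.descendant_masks()  # (n_nodes, n_tips)
    branch_per_column = np.repeat(np.arange(lengths.size), counts)
    genotypes = masks[branch_per_column].T.astype(np.uint8)
    return HaplotypeMatrix(genotypes, list(gen.labels))
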