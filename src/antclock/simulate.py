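"""Synthetic qPCR datasets and protein fixtures with known ground truth.

The qPCR generator reproduces the structure of a one-day colony time course:
three colonies sampled at 7 timepoints every 4 h across a 12:12 light:dark
day, each sample assayed in technical triplicate against a flat housekeeping
reference (EF1-alpha).  A rhythmic gene is injected on the Ct scale,

    Ct(gene, colony, zt, rep) = baseline + colony_offset
                                - amplitude_ct * cos(2*pi*(zt - acrophase)/24)
                                + Normal(0, replicate_noise_sd)

with the minus sign because lower Ct means higher expression: a gene whose
transcript peaks at ``acrophase`` has its Ct trough there.  One Ct unit of
amplitude corresponds to a two-fold peak-to-mean expression change, the
scale of oscillation the clock genes show.  Colony offsets are drawn once
per colony and shared by all genes of that colony, emulating global
template-amount differences that the reference-gene normalization removes.
Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conservation import AMINO_ACIDS, ProteinSeq
from .cosinor import DEFAULT_ZT_GRID

__all__ = [
    "GeneSpec",
    "SimConfig",
    "study_panel",
    "study_config",
    "generate_qpcr_dataset",
    "generate_domain_fixture",
]


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth expression program of one simulated gene."""

    gene: str
    baseline_ct: float
    amplitude_ct: float = 0.0
    acrophase: float = 0.0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.amplitude_ct < 0:
            raise ValueError("amplitude_ct must be >= 0")
        if self.is_reference and self.amplitude_ct != 0:
            raise ValueError(f"reference gene {self.gene!r} must have amplitude_ct = 0")
        if not (0 <= self.acrophase < 24):
            object.__setattr__(self, "acrophase", self.acrophase % 24)


def study_panel() -> tuple[GeneSpec, ...]:
    """Default gene panel mirroring an eight-gene clock screen.

    Four genes truly oscillate with a one-Ct (two-fold) amplitude or more:
    ``per`` and ``cry`` peaking in the night (ZT 18) and ``cwo`` and ``cyc``
    anti-phase to them (ZT 6).  Four genes are flat, and ``EF1a`` is the flat
    reference used for normalization.
    """
    return (
        GeneSpec("EF1a", baseline_ct=18.0, is_reference=True),
        GeneSpec("per", baseline_ct=26.0, amplitude_ct=1.2, acrophase=18.0),
        GeneSpec("cry", baseline_ct=25.0, amplitude_ct=1.5, acrophase=18.0),
        GeneSpec("cwo", baseline_ct=24.0, amplitude_ct=1.0, acrophase=6.0),
        GeneSpec("cyc", baseline_ct=25.5, amplitude_ct=1.6, acrophase=6.0),
        GeneSpec("clk", baseline_ct=24.5),
        GeneSpec("pdp1", baseline_ct=26.5),
        GeneSpec("tim", baseline_ct=27.0),
        GeneSpec("vri", baseline_ct=23.5),
    )


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated qPCR time course (defaults = study design)."""

    genes: tuple[GeneSpec, ...] = field(default_factory=study_panel)
    n_colonies: int = 3
    zts: tuple[float, ...] = DEFAULT_ZT_GRID
    n_replicates: int = 3
    colony_offset_sd: float = 0.5
    replicate_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.colony_offset_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if len(self.genes) == 0:
            raise ValueError("config needs at least one gene")
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in config")
        if len(self.zts) < 1 or np.any(np.diff(self.zts) <= 0):
            raise ValueError("zts must be a strictly increasing, non-empty grid")


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-design configuration with a chosen seed."""
    return replace(SimConfig(seed=seed), **overrides)


def generate_qpcr_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate a tidy Ct table under ``config``.

    Returns one row per technical replicate with columns
    ``gene, colony, zt, replicate, ct``, reproducible bit-for-bit from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    colonies = [f"colony{i + 1}" for i in range(config.n_colonies)]
    offsets = rng.normal(0.0, config.colony_offset_sd, config.n_colonies)
    zts = np.asarray(config.zts, float)
    rows = []
    for spec in config.genes:
        osc = -spec.amplitude_ct * np.cos(2 * np.pi * (zts - spec.acrophase) / 24.0)
        for ci, colony in enumerate(colonies):
            for zt, osc_zt in zip(zts, osc):
                noise = rng.normal(0.0, config.replicate_noise_sd, config.n_replicates)
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        (
                            spec.gene,
                            colony,
                            float(zt),
                            rep,
                            spec.baseline_ct + offsets[ci] + osc_zt + noise[rep - 1],
                        )
                    )
    return pd.DataFrame(rows, columns=["gene", "colony", "zt", "replicate", "ct"])


def generate_domain_fixture(
    length: int, n_mutations: int, seed: int = 0
) -> tuple[ProteinSeq, ProteinSeq]:
    """A random protein region and a copy with exactly ``n_mutations`` substitutions.

    No indels are introduced, so a gap-free global alignment of the pair has
    exactly ``length - n_mutations`` identical sites out of ``length``.
    Deterministic given ``seed``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= n_mutations <= length):
        raise ValueError("need 0 <= n_mutations <= length")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    residues = rng.choice(alphabet, length)
    mutated = residues.copy()
    sites = rng.choice(length, size=n_mutations, replace=False)
    for i in sites:
        choices = alphabet[alphabet != residues[i]]
        mutated[i] = rng.choice(choices)
    return (
        ProteinSeq("wild", "".join(residues)),
        ProteinSeq("mutant", "".join(mutated)),
    )
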