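"""Negative-binomial UMI count simulator with planted, recoverable structure.

The generator emulates the design of a tracheal-epithelium smoking atlas:
twelve informative donors split evenly between never-smokers and heavy
smokers, eight main epithelial populations plus three rare types (composite
rare frequency 0.8%), per-donor multiplicative batch effects, population
marker blocks, a core-plus-population-specific smoking response, a
basal-to-secretory differentiation continuum with three phase-gene waves and
a separated terminal state, and two anchor-mucin co-expression programs
(MUC5AC / MUC5B analogs) whose latent activities shift in opposite
directions with smoking.

Counts are gamma-Poisson (negative binomial) around per-gene base means with
all planted effects applied multiplicatively on the mean (natural-log
fold-changes), a lognormal per-cell depth factor, and a beta-distributed
per-cell mitochondrial fraction.  Identical seeds give bit-identical output.

Every downstream stage of the pipeline is validated against the
:class:`GroundTruth` this module returns; no external data is required
anywhere in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import (
    CellAnnotations,
    CountMatrix,
    ValidationError,
    write_annotations,
    write_count_matrix,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CoreResponseSpec",
    "UniqueResponseSpec",
    "LineageSpec",
    "MucinSpec",
    "default_config",
    "null_smoking_config",
    "marker_benchmark_config",
    "mucin_benchmark_config",
    "simulate_dataset",
    "plant_lineage",
    "plant_mucin_programs",
    "write_dataset",
]

#: the eight main populations the smoking taxonomy runs over, with three
#: rare types summing to the study's composite rare frequency of 0.008
DEFAULT_POPULATIONS: tuple[tuple[str, float], ...] = (
    ("Basal_Prolif", 0.160),
    ("Basal_Diff", 0.140),
    ("Basal_KRT14h", 0.080),
    ("KRT8_high", 0.170),
    ("Ciliated", 0.150),
    ("SMG_Basal", 0.090),
    ("SMG_Secretory", 0.080),
    ("Secretory", 0.122),
    ("Ionocyte", 0.0030),
    ("PNEC", 0.0025),
    ("Tuft", 0.0025),
)

DEFAULT_ROSTER: tuple[str, ...] = tuple(label for label, _ in DEFAULT_POPULATIONS[:8])


@dataclass(frozen=True)
class CoreResponseSpec:
    """Shared smoking-response genes planted in several populations at once."""

    n_up: int = 25
    n_down: int = 25
    n_affected_populations: int = 6
    logfc: float = 1.0


@dataclass(frozen=True)
class UniqueResponseSpec:
    """Population-private smoking-response genes (planted in exactly one)."""

    n_up: int = 10
    n_down: int = 10
    logfc: float = 1.0


@dataclass(frozen=True)
class LineageSpec:
    """A differentiation continuum through an ordered population chain.

    Non-terminal populations get true pseudotime from Gaussians centred
    evenly on [0.8, 3.2]; the terminal population is drawn from a second,
    well-separated component so that mixture-based endpoint isolation has a
    recoverable target.  Three blocks of phase genes rise and fall along the
    continuum (early / mid / terminal waves).
    """

    populations: tuple[str, ...] = ("Basal_Prolif", "Basal_Diff", "KRT8_high", "Secretory")
    n_phase_genes: int = 15
    pseudotime_noise_sd: float = 0.35
    terminal_mean: float = 8.0
    terminal_sd: float = 0.5
    phase_amplitude: float = 1.0
    phase_width: float = 2.0


@dataclass(frozen=True)
class MucinSpec:
    """Anchor-coupled co-expression programs inside the mature secretory state.

    Each program gene's log-mean follows exactly one anchor's cell-level
    latent activity with the configured ``strength``; smoking shifts the two
    anchors' latents in opposite directions (A up, B down in smokers).
    """

    host_population: str = "Secretory"
    n_program_genes: int = 25
    strength: float = 0.9
    anchor_coupling: float = 0.7
    anchor_shift: float = 0.8
    anchor_base_mean: float = 6.0
    program_base_mean: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic study."""

    n_donors_per_group: int = 6
    populations: tuple[tuple[str, float], ...] = DEFAULT_POPULATIONS
    roster: tuple[str, ...] = DEFAULT_ROSTER
    cells_per_donor: int = 420
    n_genes: int = 2000
    markers_per_population: int = 30
    marker_logfc: float = 1.5
    core_response: CoreResponseSpec = CoreResponseSpec()
    unique_response: UniqueResponseSpec = UniqueResponseSpec()
    nb_dispersion: float = 0.5
    depth_lognormal: tuple[float, float] = (0.0, 0.35)
    mito_gene_count: int = 10
    mito_fraction_beta: tuple[float, float] = (2.0, 38.0)
    lineage: LineageSpec | None = LineageSpec()
    mucin: MucinSpec | None = MucinSpec()
    donor_effect_sd: float = 0.15
    base_mean_lognormal: tuple[float, float] = (-1.2, 1.0)
    planted_base_mean_range: tuple[float, float] = (0.4, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.array([f for _, f in self.populations], dtype=float)
        if not np.all((freqs > 0) & (freqs < 1)):
            raise ValidationError("population frequencies must lie in (0, 1)")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"population frequencies sum to {freqs.sum():.6f}, not 1"
            )
        labels = [p for p, _ in self.populations]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate population labels")
        unknown = set(self.roster) - set(labels)
        if unknown:
            raise ValidationError(f"roster population(s) not defined: {sorted(unknown)}")
        if self.core_response.n_affected_populations > len(self.roster):
            raise ValidationError("core response affects more populations than roster has")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.mucin is not None and not 0 <= self.mucin.strength <= 1:
            raise ValidationError("mucin program strength must lie in [0, 1]")
        if self.lineage is not None:
            bad = set(self.lineage.populations) - set(labels)
            if bad:
                raise ValidationError(f"lineage population(s) not defined: {sorted(bad)}")
        if self._planted_gene_count() > self.n_genes:
            raise ValidationError(
                f"planted genes ({self._planted_gene_count()}) exceed n_genes ({self.n_genes})"
            )

    def _planted_gene_count(self) -> int:
        n = self.markers_per_population * len(self.populations)
        n += self.core_response.n_up + self.core_response.n_down
        n += (self.unique_response.n_up + self.unique_response.n_down) * len(self.roster)
        if self.lineage is not None:
            n += 3 * self.lineage.n_phase_genes
        if self.mucin is not None:
            n += 2 * self.mucin.n_program_genes + 2
        n += self.mito_gene_count
        return n

    @property
    def population_labels(self) -> list[str]:
        return [p for p, _ in self.populations]


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The full synthetic study at its default conditions."""
    return replace(SimConfig(), seed=seed, **overrides)


def null_smoking_config(seed: int = 0, *, donor_effect_sd: float = 0.0) -> SimConfig:
    """No planted effects at all: the exchangeable type-I-error condition.

    Marker, smoking, lineage, mucin and donor effect sizes are all zero, so
    cells are exchangeable between smoking groups and any flagged gene is a
    false positive.  Passing a positive ``donor_effect_sd`` re-introduces
    batch structure, under which *no* cell-level test is calibrated across
    donors (pseudoreplication); that setting probes robustness, not
    calibration.
    """
    return SimConfig(
        seed=seed,
        marker_logfc=0.0,
        core_response=CoreResponseSpec(logfc=0.0),
        unique_response=UniqueResponseSpec(logfc=0.0),
        lineage=None,
        mucin=None,
        donor_effect_sd=donor_effect_sd,
    )


def marker_benchmark_config(seed: int = 0) -> SimConfig:
    """Marker blocks only (no lineage / mucin structure), for marker recovery.

    Continuum and program genes are genuinely population-restricted
    expression and would count against measured precision despite being
    biologically real markers; the benchmark isolates the planted blocks.
    """
    return SimConfig(
        seed=seed,
        lineage=None,
        mucin=None,
        core_response=CoreResponseSpec(logfc=0.0),
        unique_response=UniqueResponseSpec(logfc=0.0),
    )


def mucin_benchmark_config(seed: int = 0) -> SimConfig:
    """A secretory-enriched study sized so ~2,000 cells carry the programs."""
    pops = (
        ("Basal_Diff", 0.30),
        ("Secretory", 0.70),
    )
    return SimConfig(
        seed=seed,
        populations=pops,
        roster=("Basal_Diff", "Secretory"),
        cells_per_donor=250,
        n_genes=2000,
        core_response=CoreResponseSpec(n_up=5, n_down=5, n_affected_populations=2),
        unique_response=UniqueResponseSpec(n_up=2, n_down=2),
        lineage=None,
        mucin=MucinSpec(),
    )


@dataclass
class GroundTruth:
    """The generator's planted structure, used as the downstream oracle."""

    gene_ids: list[str]
    markers: dict[str, list[str]]
    core_up: list[str]
    core_down: list[str]
    core_affected: dict[str, list[str]]
    unique_up: dict[str, list[str]]
    unique_down: dict[str, list[str]]
    phase_genes: dict[int, list[str]]
    anchor_a: str | None
    anchor_b: str | None
    program_a: list[str]
    program_b: list[str]
    mito_genes: list[str]
    cells: pd.DataFrame  # cell_id, donor, smoking, population, true_pseudotime, latent_a, latent_b
    terminal_population: str | None

    def roles(self) -> pd.DataFrame:
        """Long-format per-gene role table (a gene may hold several roles)."""
        rows: list[tuple[str, str, str]] = []
        for pop, genes in self.markers.items():
            rows += [(g, "marker", pop) for g in genes]
        rows += [(g, "core_up", "") for g in self.core_up]
        rows += [(g, "core_down", "") for g in self.core_down]
        for pop, genes in self.unique_up.items():
            rows += [(g, "unique_up", pop) for g in genes]
        for pop, genes in self.unique_down.items():
            rows += [(g, "unique_down", pop) for g in genes]
        for phase, genes in self.phase_genes.items():
            rows += [(g, f"phase_{phase}", "") for g in genes]
        rows += [(g, "program_a", "") for g in self.program_a]
        rows += [(g, "program_b", "") for g in self.program_b]
        if self.anchor_a:
            rows.append((self.anchor_a, "anchor_a", ""))
        if self.anchor_b:
            rows.append((self.anchor_b, "anchor_b", ""))
        return pd.DataFrame(rows, columns=["gene", "role", "population"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "markers": self.markers,
            "core_up": self.core_up,
            "core_down": self.core_down,
            "core_affected": self.core_affected,
            "unique_up": self.unique_up,
            "unique_down": self.unique_down,
            "phase_genes": {str(k): v for k, v in self.phase_genes.items()},
            "anchor_a": self.anchor_a,
            "anchor_b": self.anchor_b,
            "program_a": self.program_a,
            "program_b": self.program_b,
            "mito_genes": self.mito_genes,
            "terminal_population": self.terminal_population,
            "cells": self.cells.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# role assignment


def _assign_roles(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    labels = config.population_labels
    cursor = 0

    def take(n: int, namer) -> list[str]:
        nonlocal cursor
        names = [namer(i) for i in range(cursor, cursor + n)]
        cursor += n
        return names

    markers = {
        pop: take(config.markers_per_population, lambda i, p=pop: f"MK_{p}_{i:04d}")
        for pop in labels
    }
    core = config.core_response
    core_up = take(core.n_up, lambda i: f"CORE_UP_{i:04d}")
    core_down = take(core.n_down, lambda i: f"CORE_DN_{i:04d}")
    core_affected = {
        g: sorted(rng.choice(config.roster, size=core.n_affected_populations, replace=False))
        for g in core_up + core_down
    }
    uq = config.unique_response
    unique_up = {p: take(uq.n_up, lambda i, p=p: f"UQ_{p}_UP_{i:04d}") for p in config.roster}
    unique_down = {p: take(uq.n_down, lambda i, p=p: f"UQ_{p}_DN_{i:04d}") for p in config.roster}

    phase_genes: dict[int, list[str]] = {}
    if config.lineage is not None:
        for phase in (1, 2, 3):
            phase_genes[phase] = take(
                config.lineage.n_phase_genes, lambda i, ph=phase: f"PHASE{ph}_{i:04d}"
            )

    anchor_a = anchor_b = None
    program_a: list[str] = []
    program_b: list[str] = []
    if config.mucin is not None:
        anchor_a, anchor_b = "MUC5AC", "MUC5B"
        cursor += 2
        program_a = take(config.mucin.n_program_genes, lambda i: f"PRA_{i:04d}")
        program_b = take(config.mucin.n_program_genes, lambda i: f"PRB_{i:04d}")

    mito = take(config.mito_gene_count, lambda i: f"MT-SIM{i:02d}")

    gene_ids = (
        [g for gs in markers.values() for g in gs]
        + core_up
        + core_down
        + [g for gs in unique_up.values() for g in gs]
        + [g for gs in unique_down.values() for g in gs]
        + [g for gs in phase_genes.values() for g in gs]
        + ([anchor_a, anchor_b] if anchor_a else [])
        + program_a
        + program_b
        + mito
    )
    n_background = config.n_genes - len(gene_ids)
    gene_ids += [f"G{i:05d}" for i in range(n_background)]

    return GroundTruth(
        gene_ids=gene_ids,
        markers=markers,
        core_up=core_up,
        core_down=core_down,
        core_affected=core_affected,
        unique_up=unique_up,
        unique_down=unique_down,
        phase_genes=phase_genes,
        anchor_a=anchor_a,
        anchor_b=anchor_b,
        program_a=program_a,
        program_b=program_b,
        mito_genes=mito,
        cells=pd.DataFrame(),
        terminal_population=(
            config.lineage.populations[-1] if config.lineage is not None else None
        ),
    )


def _assign_cells(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    donors = [f"N{i + 1}" for i in range(config.n_donors_per_group)] + [
        f"S{i + 1}" for i in range(config.n_donors_per_group)
    ]
    smoking = ["never"] * config.n_donors_per_group + ["heavy"] * config.n_donors_per_group
    labels = config.population_labels
    freqs = np.array([f for _, f in config.populations])
    rows = []
    for donor, habit in zip(donors, smoking):
        pops = rng.choice(len(labels), size=config.cells_per_donor, p=freqs)
        for j, p in enumerate(pops):
            rows.append((f"{donor}_C{j:04d}", donor, habit, labels[p]))
    cells = pd.DataFrame(rows, columns=["cell_id", "donor", "smoking", "population"])
    cells["true_pseudotime"] = np.nan
    cells["latent_a"] = np.nan
    cells["latent_b"] = np.nan
    return cells


# ---------------------------------------------------------------------------
# structure planting


def plant_lineage(config: SimConfig, truth: GroundTruth, rng: np.random.Generator | None = None) -> GroundTruth:
    """Assign true pseudotime along the configured differentiation chain.

    Non-terminal populations receive Gaussian pseudotime around centres
    evenly spaced on [0.8, 3.2] (clipped to [0, 4]); the terminal population
    is drawn from the separated endpoint component.
    """
    spec = config.lineage
    if spec is None:
        return truth
    if rng is None:
        rng = np.random.default_rng(config.seed + 101)
    known = set(truth.cells["population"].unique()) | set(config.population_labels)
    bad = set(spec.populations) - known
    if bad:
        raise ValidationError(f"lineage references unknown population(s): {sorted(bad)}")
    non_terminal = list(spec.populations[:-1])
    if len(non_terminal) == 1:
        centers = {non_terminal[0]: 2.0}
    else:
        centers = dict(zip(non_terminal, np.linspace(0.8, 3.2, len(non_terminal))))
    cells = truth.cells
    pt = np.full(len(cells), np.nan)
    for pop, center in centers.items():
        mask = (cells["population"] == pop).to_numpy()
        draw = rng.normal(center, spec.pseudotime_noise_sd, size=int(mask.sum()))
        pt[mask] = np.clip(draw, 0.0, 4.0)
    term_mask = (cells["population"] == spec.populations[-1]).to_numpy()
    draw = rng.normal(spec.terminal_mean, spec.terminal_sd, size=int(term_mask.sum()))
    pt[term_mask] = np.clip(draw, 0.0, None)
    cells = cells.copy()
    cells["true_pseudotime"] = pt
    truth.cells = cells
    truth.terminal_population = spec.populations[-1]
    return truth


def phase_log_effect(t: np.ndarray, phase: int, spec: LineageSpec) -> np.ndarray:
    """Planted log-scale mean bump of a phase gene at pseudotime ``t``.

    Gaussian waves centred early (1.0), mid (4.0) and late (6.0) so each
    block rises then falls within its phase of the continuum.  The late
    wave rises gradually from mid-continuum into the terminal state,
    keeping the planted expression a genuine gradient rather than a
    terminal-only jump.
    """
    centers = {1: 1.0, 2: 4.0, 3: 6.0}
    t = np.asarray(t, dtype=float)
    return spec.phase_amplitude * np.exp(
        -((t - centers[phase]) ** 2) / (2.0 * spec.phase_width**2)
    )


def plant_mucin_programs(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw per-cell anchor latents in the host population.

    Latent activity is standard normal plus an opposite-signed smoking shift
    (anchor A up, anchor B down in smokers); program genes couple to exactly
    one latent when count means are built.
    """
    spec = config.mucin
    if spec is None:
        return truth
    if not 0 <= spec.strength <= 1:
        raise ValidationError("mucin program strength must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed + 202)
    cells = truth.cells.copy()
    host = (cells["population"] == spec.host_population).to_numpy()
    smoker = (cells["smoking"] == "heavy").to_numpy()
    n = int(host.sum())
    la = rng.normal(size=n) + spec.anchor_shift * smoker[host]
    lb = rng.normal(size=n) - spec.anchor_shift * smoker[host]
    latent_a = np.full(len(cells), np.nan)
    latent_b = np.full(len(cells), np.nan)
    latent_a[host] = la
    latent_b[host] = lb
    cells["latent_a"] = latent_a
    cells["latent_b"] = latent_b
    truth.cells = cells
    return truth


# ---------------------------------------------------------------------------
# count sampling


def _build_log_means(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Log-scale mean matrix (genes × cells) before depth and mito handling."""
    genes = truth.gene_ids
    gidx = {g: i for i, g in enumerate(genes)}
    cells = truth.cells
    n_genes, n_cells = len(genes), len(cells)

    # base means: background lognormal; planted-role genes re-drawn from a
    # moderate-expression band so detection gates are realistically passable
    mu_log, sd_log = config.base_mean_lognormal
    base = rng.lognormal(mu_log, sd_log, size=n_genes)
    planted = sorted(
        {
            g
            for g in genes
            if not g.startswith("G") and g not in truth.mito_genes
        },
        key=lambda g: gidx[g],
    )
    lo, hi = config.planted_base_mean_range
    base[[gidx[g] for g in planted]] = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=len(planted))
    )
    log_mu = np.tile(np.log(base)[:, None], (1, n_cells))

    pop = cells["population"].to_numpy()
    smoker = (cells["smoking"] == "heavy").to_numpy()
    donor = cells["donor"].to_numpy()

    # donor batch effects: lognormal per donor-gene
    if config.donor_effect_sd > 0:
        for d in pd.unique(donor):
            eff = rng.normal(0.0, config.donor_effect_sd, size=n_genes)
            log_mu[:, donor == d] += eff[:, None]
    else:
        # keep the stream position independent of the sd value
        for _ in pd.unique(donor):
            rng.normal(0.0, 1.0, size=n_genes)

    # population marker blocks; along the lineage, marker expression is
    # graded by pseudotime proximity to the population's stage (adjacent
    # states share partial marker expression, as transitional states do),
    # so the continuum is a genuine expression gradient
    lineage_centers: dict[str, float] = {}
    if config.lineage is not None:
        spec = config.lineage
        non_terminal = list(spec.populations[:-1])
        if len(non_terminal) == 1:
            lineage_centers[non_terminal[0]] = 2.0
        else:
            lineage_centers.update(
                zip(non_terminal, np.linspace(0.8, 3.2, len(non_terminal)))
            )
        lineage_centers[spec.populations[-1]] = spec.terminal_mean
    t_all = cells["true_pseudotime"].to_numpy()
    on_lineage_cells = ~np.isnan(t_all)
    for p, marker_genes in truth.markers.items():
        rows = [gidx[g] for g in marker_genes]
        if p in lineage_centers:
            centers_sorted = sorted(lineage_centers.values())
            c_p = lineage_centers[p]
            others = [c for c in centers_sorted if c != c_p]
            delta = min(abs(c_p - c) for c in others)
            w = np.clip(1.0 - np.abs(t_all[on_lineage_cells] - c_p) / (2.0 * delta), 0.0, 1.0)
            log_mu[np.ix_(rows, on_lineage_cells)] += config.marker_logfc * w[None, :]
        else:
            cols = pop == p
            if cols.any():
                log_mu[np.ix_(rows, cols)] += config.marker_logfc

    # core smoking response (affected populations only)
    for g in truth.core_up + truth.core_down:
        sign = 1.0 if g in set(truth.core_up) else -1.0
        cols = smoker & np.isin(pop, truth.core_affected[g])
        if cols.any():
            log_mu[gidx[g], cols] += sign * config.core_response.logfc

    # unique smoking response (one population each)
    for p in config.roster:
        cols_up = smoker & (pop == p)
        if cols_up.any():
            for g in truth.unique_up[p]:
                log_mu[gidx[g], cols_up] += config.unique_response.logfc
            for g in truth.unique_down[p]:
                log_mu[gidx[g], cols_up] -= config.unique_response.logfc

    # lineage phase waves
    if config.lineage is not None:
        t = cells["true_pseudotime"].to_numpy()
        on_lineage = ~np.isnan(t)
        for phase, phase_gene_list in truth.phase_genes.items():
            bump = phase_log_effect(t[on_lineage], phase, config.lineage)
            log_mu[np.ix_([gidx[g] for g in phase_gene_list], on_lineage)] += bump[None, :]

    # mucin anchors and programs in the host population
    if config.mucin is not None:
        spec = config.mucin
        host = (pop == spec.host_population)
        la = cells["latent_a"].to_numpy()[host]
        lb = cells["latent_b"].to_numpy()[host]
        ia, ib = gidx[truth.anchor_a], gidx[truth.anchor_b]
        # anchors highly expressed in host cells, nearly silent elsewhere
        log_mu[ia, :] = np.log(0.05)
        log_mu[ib, :] = np.log(0.05)
        log_mu[ia, host] = np.log(spec.anchor_base_mean) + spec.anchor_coupling * la
        log_mu[ib, host] = np.log(spec.anchor_base_mean) + spec.anchor_coupling * lb
        for g_list, latent in ((truth.program_a, la), (truth.program_b, lb)):
            rows = [gidx[g] for g in g_list]
            log_mu[np.ix_(rows, host)] = (
                np.log(spec.program_base_mean)
                + spec.strength * spec.anchor_coupling * latent[None, :]
            )
    return log_mu


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, CellAnnotations, GroundTruth]:
    """Draw one full synthetic study.

    Returns the UMI count matrix (genes × cells), cell annotations and the
    planted ground truth.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _assign_roles(config, rng)
    truth.cells = _assign_cells(config, rng)
    truth = plant_lineage(config, truth, rng)
    truth = plant_mucin_programs(config, truth, rng)

    log_mu = _build_log_means(config, truth, rng)
    n_genes, n_cells = log_mu.shape

    # per-cell sequencing depth (lognormal exposure factor)
    mean_log, sd_log = config.depth_lognormal
    depth = rng.lognormal(mean_log, sd_log, size=n_cells)
    mu = np.exp(log_mu) * depth[None, :]

    # mitochondrial genes: per-cell beta fraction of the cell's total output
    mito_rows = [truth.gene_ids.index(g) for g in truth.mito_genes]
    if mito_rows:
        a, b = config.mito_fraction_beta
        frac = rng.beta(a, b, size=n_cells)
        non_mito_total = np.delete(mu, mito_rows, axis=0).sum(axis=0)
        mito_total = frac / (1.0 - frac) * non_mito_total
        mu[mito_rows, :] = mito_total[None, :] / len(mito_rows)

    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu * config.nb_dispersion)
    counts = rng.poisson(lam)

    matrix = CountMatrix(sp.csr_matrix(counts), truth.gene_ids, list(truth.cells["cell_id"]))
    ann_table = truth.cells[["cell_id", "donor", "smoking", "population"]].copy()
    ann_table["excluded_flag"] = False
    annotations = CellAnnotations(ann_table)
    return matrix, annotations, truth


def write_dataset(
    out_dir: str | Path,
    counts: CountMatrix,
    annotations: CellAnnotations,
    truth: GroundTruth | None = None,
) -> None:
    """Write the MatrixMarket trio, annotation TSV and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(counts, out)
    write_annotations(annotations, out / "annotations.tsv")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
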