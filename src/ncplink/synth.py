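"""Synthetic inputs with known ground truth for every pipeline stage.

Generates relationship tables over two lineages with configurable sign
probabilities, occurrence grids with controlled per-pixel richness, and
skewed reference-count tables — all reproducible from explicit seeds
(seeds are arguments, never global state).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .catalog import LINEAGES, NCPCatalog, applicability_mask, load_catalog
from .table import (PLANT_SUBGROUPS, VERTEBRATE_SUBGROUPS, RelationshipTable)

ProbSpec = Union[float, Mapping[str, float]]

RICHNESS_MODELS = ("uniform", "gradient")
COUNT_DISTRIBUTIONS = ("heavy_tail", "uniform")


@dataclass(frozen=True)
class TableGeneratorSpec:
    """Sign-probability model for a synthetic relationship table.

    ``p_positive``/``p_negative``/``p_na`` may be scalars (same for every
    NCP) or dicts keyed by ncp_id; the remaining mass is neutral.  A
    positive ``p_negative`` on an NCP that does not admit negatives is an
    error — the generator never plants invalid cells.
    """

    n_tracheophytes: int
    n_vertebrates: int
    p_positive: ProbSpec = 0.3
    p_negative: ProbSpec = 0.05
    p_na: ProbSpec = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_tracheophytes < 0 or self.n_vertebrates < 0:
            raise ValueError("species counts must be non-negative")
        if self.n_tracheophytes + self.n_vertebrates == 0:
            raise ValueError("at least one species is required")

    def probs_for(self, ncp_id: str) -> tuple:
        def pick(spec: ProbSpec) -> float:
            return float(spec[ncp_id]) if isinstance(spec, Mapping) else float(spec)
        p_pos, p_neg, p_na = (pick(self.p_positive), pick(self.p_negative),
                              pick(self.p_na))
        for name, p in (("p_positive", p_pos), ("p_negative", p_neg),
                        ("p_na", p_na)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} for {ncp_id!r} out of [0, 1]: {p}")
        if p_pos + p_neg + p_na > 1 + 1e-12:
            raise ValueError(
                f"probabilities for {ncp_id!r} sum to {p_pos + p_neg + p_na} > 1")
        return p_pos, p_neg, p_na


def _species_frame(n_trach: int, n_vert: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    subgroup_cycles = {
        "tracheophyte": itertools.cycle(PLANT_SUBGROUPS),
        "vertebrate": itertools.cycle(VERTEBRATE_SUBGROUPS),
    }
    for lineage, n, prefix in (("tracheophyte", n_trach, "t"),
                               ("vertebrate", n_vert, "v")):
        for i in range(n):
            rows.append({
                "species_id": f"{prefix}{i + 1:05d}",
                "scientific_name": f"Genus {prefix}species{i + 1}",
                "lineage": lineage,
                "subgroup": next(subgroup_cycles[lineage]),
                "class": "", "order": "", "family": "",
                "iucn_status": "LC",
                "n_occurrences": int(rng.integers(10, 5000)),
                "alien": False,
            })
    return pd.DataFrame(rows)


def generate_table(spec: TableGeneratorSpec, catalog: NCPCatalog):
    """Draw a relationship table plus its exact ground-truth tallies.

    Returns
    -------
    (RelationshipTable, DataFrame)
        The table and a tally frame with one row per (ncp_id, lineage):
        true n_positive / n_negative / n_neutral / n_na counts, matching
        what :func:`~ncplink.table.ncp_summary` must report.
    """
    # validate probabilities up front (including the negative-allowed gate)
    for ncp in catalog:
        p_pos, p_neg, p_na = spec.probs_for(ncp.ncp_id)
        if p_neg > 0 and not ncp.negative_allowed:
            raise ValueError(
                f"p_negative > 0 for {ncp.ncp_id!r}, which does not admit "
                "negative values")

    rng = np.random.default_rng(spec.seed)
    species = _species_frame(spec.n_tracheophytes, spec.n_vertebrates, rng)
    cells = pd.DataFrame(np.nan, index=species["species_id"],
                         columns=catalog.ncp_ids)
    tallies = []
    for ncp in catalog:
        p_pos, p_neg, p_na = spec.probs_for(ncp.ncp_id)
        for lineage in LINEAGES:
            ids = species.loc[species["lineage"] == lineage, "species_id"]
            if not ncp.applies_to(lineage) or ids.empty:
                continue
            u = rng.random(len(ids))
            vals = np.zeros(len(ids))
            vals[u < p_pos] = 1.0
            vals[(u >= p_pos) & (u < p_pos + p_neg)] = -1.0
            na = (u >= p_pos + p_neg) & (u < p_pos + p_neg + p_na)
            vals[na] = np.nan
            cells.loc[ids, ncp.ncp_id] = vals
            tallies.append({
                "ncp_id": ncp.ncp_id, "lineage": lineage,
                "n_positive": int(np.nansum(vals == 1)),
                "n_negative": int(np.nansum(vals == -1)),
                "n_neutral": int(np.nansum(vals == 0)),
                "n_na": int(np.isnan(vals).sum()),
            })
    table = RelationshipTable(catalog, species, cells)
    return table, pd.DataFrame(tallies)


def paper_shaped_table(seed: int = 0) -> RelationshipTable:
    """Preset emulating the real study's shape: 1816 + 250 species,
    the built-in 17-NCP catalog, and exactly 208 no-information cells
    placed uniformly at random among the applicable pairs — so
    ``count_relationships`` returns (31098, 31306).
    """
    catalog = load_catalog("builtin")
    spec = TableGeneratorSpec(
        n_tracheophytes=1816, n_vertebrates=250,
        p_positive=0.25,
        p_negative={n.ncp_id: (0.05 if n.negative_allowed else 0.0)
                    for n in catalog},
        p_na=0.0, seed=seed)
    table, _ = generate_table(spec, catalog)
    # plant the 208 NA_no_info cells among applicable pairs
    rng = np.random.default_rng(seed + 1)
    app = table.applicable_matrix().to_numpy()
    flat = np.flatnonzero(app)
    chosen = rng.choice(flat, size=208, replace=False)
    arr = table.cells.to_numpy()
    arr.flat[chosen] = np.nan
    table.cells.iloc[:, :] = arr
    return table


@dataclass(frozen=True)
class GridGeneratorSpec:
    """Occurrence-grid model: geometry plus a per-pixel richness law.

    ``richness_model`` is ``uniform`` (every pixel gets exactly
    ``richness_min`` distinct species) or ``gradient`` (Poisson draws whose
    mean increases linearly from ``richness_min`` at row 0 to
    ``richness_max`` at the last row, clipped to the species pool).
    """

    nrows: int
    ncols: int
    richness_model: str = "uniform"
    richness_min: int = 2
    richness_max: int = 2
    cell_size: float = 1.0
    x0: float = 0.0
    y0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one pixel")
        if self.richness_model not in RICHNESS_MODELS:
            raise ValueError(f"unknown richness model {self.richness_model!r}")
        if self.richness_min < 0 or self.richness_max < self.richness_min:
            raise ValueError("need 0 <= richness_min <= richness_max")


def generate_occurrences(spec: GridGeneratorSpec,
                         species_ids: Iterable[str]) -> pd.DataFrame:
    """Draw occurrence records (species_id, x, y, year) over the grid.

    Every pixel's distinct-species count follows the richness model; points
    fall strictly inside their pixel so rasterization recovers the planted
    structure exactly.
    """
    pool = list(species_ids)
    if not pool:
        raise ValueError("species pool is empty")
    if spec.richness_model == "uniform" and spec.richness_min > len(pool):
        raise ValueError("uniform richness exceeds the species pool")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for r in range(spec.nrows):
        if spec.richness_model == "uniform":
            lam = None
        else:
            frac = r / (spec.nrows - 1) if spec.nrows > 1 else 0.0
            lam = spec.richness_min + frac * (spec.richness_max - spec.richness_min)
        for c in range(spec.ncols):
            if lam is None:
                k = spec.richness_min
            else:
                k = min(int(rng.poisson(lam)), len(pool))
            chosen = rng.choice(pool, size=k, replace=False)
            x_lo = spec.x0 + c * spec.cell_size
            y_lo = spec.y0 + (spec.nrows - 1 - r) * spec.cell_size
            for sid in chosen:
                rows.append({
                    "species_id": sid,
                    "x": x_lo + rng.random() * spec.cell_size,
                    "y": y_lo + rng.random() * spec.cell_size,
                    "year": int(rng.integers(1970, 2021)),
                })
    return pd.DataFrame(rows, columns=["species_id", "x", "y", "year"])


def generate_reference_counts(n: int, distribution: str = "heavy_tail",
                              seed: int = 0,
                              species_ids: Optional[Iterable[str]] = None) -> dict:
    """Draw a species_id -> count table.

    ``heavy_tail`` uses a discretised lognormal (ties rare, so the
    strictly-above-Q3 rule flags about a quarter of the species);
    ``uniform`` draws integers in [0, 10000].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if distribution not in COUNT_DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    if distribution == "heavy_tail":
        counts = np.floor(np.exp(rng.normal(3.0, 1.5, size=n))).astype(int)
    else:
        counts = rng.integers(0, 10001, size=n)
    ids = list(species_ids) if species_ids is not None else [
        f"s{i + 1:05d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("species_ids length must equal n")
    return dict(zip(ids, (int(c) for c in counts)))
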