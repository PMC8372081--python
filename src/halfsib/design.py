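"""Factorial half-sib/full-sib breeding designs and experimental allocations.

A North Carolina II (factorial) mating design crosses every sire with every
dam inside a breeding block, producing paternal half-sib, maternal half-sib
and full-sib families that allow additive, maternal and dominance variance
to be separated downstream.  This module builds the pedigree, allocates
full-sib families to embryonic rearing units (water treatment x replicate
shelf) and to individually-reared field containers (spatial blocks within
each rearing environment), and models attrition (failed crosses, lost
units) stochastically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BreedingDesign",
    "make_design",
    "allocate_embryo_units",
    "apply_attrition",
    "allocate_field",
    "default_environments",
]


def default_environments(n: int) -> list[str]:
    """Environment/treatment labels: REF/ASH for the two-site layout, else E1..En."""
    if n == 2:
        return ["REF", "ASH"]
    return [f"E{i + 1}" for i in range(n)]


@dataclass
class BreedingDesign:
    """A factorial (within-block fully crossed) mating design.

    Attributes
    ----------
    populations : list of str
        Population labels (e.g. ``["REF", "ASH"]``).
    blocks : DataFrame with columns ``population, block``
        One row per breeding block.
    sires, dams : DataFrame with columns ``id, population, block``
        Parent rosters; ids look like ``REF-B1-S3`` / ``REF-B1-D2``.
    crosses : DataFrame with columns ``family, sire, dam, population, block``
        One row per full-sib family (one sire x dam cross).
    """

    populations: list[str]
    blocks: pd.DataFrame
    sires: pd.DataFrame
    dams: pd.DataFrame
    crosses: pd.DataFrame

    @property
    def n_families(self) -> int:
        return len(self.crosses)

    def families_per_block(self) -> pd.Series:
        return self.crosses.groupby(["population", "block"]).size()

    def validate(self) -> None:
        """Check the factorial invariants; raise ``ValueError`` on violation."""
        sire_info = self.sires.set_index("id")
        dam_info = self.dams.set_index("id")
        for row in self.crosses.itertuples():
            s = sire_info.loc[row.sire]
            d = dam_info.loc[row.dam]
            if not (s.population == d.population == row.population):
                raise ValueError(f"cross {row.family} pairs parents across populations")
            if not (s.block == d.block == row.block):
                raise ValueError(f"cross {row.family} pairs parents across blocks")
        if self.crosses.duplicated(["sire", "dam"]).any():
            raise ValueError("duplicate sire x dam cross")

    def drop_blocks(self, blocks: list[tuple[str, int]]) -> "BreedingDesign":
        """Return a design with the given ``(population, block)`` pairs removed.

        Mirrors field studies where whole breeding blocks are excluded
        (e.g. low fertilization success in part of one population).
        """
        dropped = set(blocks)

        def keep(df: pd.DataFrame) -> pd.DataFrame:
            mask = [
                (p, b) not in dropped
                for p, b in zip(df["population"], df["block"])
            ]
            return df.loc[mask].reset_index(drop=True)

        return BreedingDesign(
            populations=self.populations,
            blocks=keep(self.blocks),
            sires=keep(self.sires),
            dams=keep(self.dams),
            crosses=keep(self.crosses),
        )

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sires.to_csv(outdir / "sires.csv", index=False)
        self.dams.to_csv(outdir / "dams.csv", index=False)
        self.crosses.to_csv(outdir / "crosses.csv", index=False)


def make_design(
    n_populations: int,
    blocks_per_population: int,
    sires_per_block: int,
    dams_per_block: int,
    population_labels: list[str] | None = None,
) -> BreedingDesign:
    """Build the factorial breeding design.

    Every block holds ``sires_per_block`` sires and ``dams_per_block`` dams,
    fully crossed, so the total family count is the product of all four
    arguments.  The canonical field layout is ``make_design(2, 4, 8, 2)``:
    two populations, four breeding blocks each, 8 sires x 2 dams per block
    = 16 full-sib families per block, 64 per population, 128 total.
    """
    for name, v in [
        ("n_populations", n_populations),
        ("blocks_per_population", blocks_per_population),
        ("sires_per_block", sires_per_block),
        ("dams_per_block", dams_per_block),
    ]:
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")

    if population_labels is None:
        population_labels = (
            default_environments(n_populations)
            if n_populations == 2
            else [f"P{i + 1}" for i in range(n_populations)]
        )
    if len(population_labels) != n_populations:
        raise ValueError("population_labels length must equal n_populations")

    blocks, sires, dams, crosses = [], [], [], []
    for pop in population_labels:
        for b in range(1, blocks_per_population + 1):
            blocks.append({"population": pop, "block": b})
            block_sires = [
                {"id": f"{pop}-B{b}-S{i + 1}", "population": pop, "block": b}
                for i in range(sires_per_block)
            ]
            block_dams = [
                {"id": f"{pop}-B{b}-D{j + 1}", "population": pop, "block": b}
                for j in range(dams_per_block)
            ]
            sires.extend(block_sires)
            dams.extend(block_dams)
            for s in block_sires:
                for d in block_dams:
                    crosses.append(
                        {
                            "family": f"{s['id']}x{d['id'].rsplit('-', 1)[-1]}",
                            "sire": s["id"],
                            "dam": d["id"],
                            "population": pop,
                            "block": b,
                        }
                    )

    return BreedingDesign(
        populations=list(population_labels),
        blocks=pd.DataFrame(blocks),
        sires=pd.DataFrame(sires),
        dams=pd.DataFrame(dams),
        crosses=pd.DataFrame(crosses),
    )


def allocate_embryo_units(
    design: BreedingDesign,
    n_treatments: int,
    n_replicates: int,
    treatments: list[str] | None = None,
    n_initial: int = 40,
) -> pd.DataFrame:
    """One embryonic rearing unit per (family, water treatment, replicate shelf).

    Returns a DataFrame with columns ``family, sire, dam, population, block,
    treatment, replicate, n_initial, n_survived`` (``n_survived`` starts as NA
    and is filled by the embryo-survival simulator or by observed data).
    """
    if design.n_families == 0:
        raise ValueError("design has no crosses")
    if n_treatments < 1 or n_replicates < 1:
        raise ValueError("n_treatments and n_replicates must be >= 1")
    if treatments is None:
        treatments = default_environments(n_treatments)
    if len(treatments) != n_treatments:
        raise ValueError("treatments length must equal n_treatments")

    rows = []
    for cross in design.crosses.itertuples():
        for tr in treatments:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "family": cross.family,
                        "sire": cross.sire,
                        "dam": cross.dam,
                        "population": cross.population,
                        "block": cross.block,
                        "treatment": tr,
                        "replicate": rep,
                        "n_initial": n_initial,
                        "n_survived": pd.NA,
                    }
                )
    return pd.DataFrame(rows)


def apply_attrition(
    design: BreedingDesign,
    cross_failure_prob: float | dict[str, float],
    unit_shortfall_prob: float,
    seed: int,
    units: pd.DataFrame | None = None,
) -> tuple[BreedingDesign, pd.DataFrame | None]:
    """Remove whole crosses and individual embryo units at the given rates.

    ``cross_failure_prob`` may be a single probability or a per-population
    mapping (field datasets often lose crosses in only one population).
    Units belonging to a failed cross are removed as well; surviving units
    are then independently dropped with ``unit_shortfall_prob``.
    Deterministic under a fixed ``seed``.
    """
    probs = (
        cross_failure_prob
        if isinstance(cross_failure_prob, dict)
        else {p: cross_failure_prob for p in design.populations}
    )
    for p, v in list(probs.items()) + [("unit", unit_shortfall_prob)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability for {p!r} out of [0, 1]: {v}")

    rng = np.random.default_rng(seed)
    p_fail = design.crosses["population"].map(probs).fillna(0.0).to_numpy(float)
    keep_cross = rng.random(len(p_fail)) >= p_fail
    kept = design.crosses.loc[keep_cross].reset_index(drop=True)
    new_design = BreedingDesign(
        populations=design.populations,
        blocks=design.blocks,
        sires=design.sires,
        dams=design.dams,
        crosses=kept,
    )

    new_units = None
    if units is not None:
        surviving = units["family"].isin(set(kept["family"]))
        new_units = units.loc[surviving].reset_index(drop=True)
        keep_unit = rng.random(len(new_units)) >= unit_shortfall_prob
        new_units = new_units.loc[keep_unit].reset_index(drop=True)
    return new_design, new_units


def allocate_field(
    design: BreedingDesign,
    n_spatial_blocks: int,
    seed: int,
    environments: list[str] | None = None,
    units: pd.DataFrame | None = None,
    availability: pd.DataFrame | None = None,
    n_containers_per_block: int | None = None,
) -> pd.DataFrame:
    """Assign one larva per family to each spatial block of its environment.

    Each family x water-treatment combination from the embryonic stage is
    carried into the matching field environment (reciprocal transplant:
    rearing environment equals the embryonic water source).  Families get
    one container per spatial block; container positions within a block are
    a seeded random permutation, mirroring random assignment of families to
    containers in the field.

    ``availability`` (columns ``family, environment, n_available``) caps the
    number of blocks a family can fill, emulating families that produced
    fewer larvae than replicates.  Returns a DataFrame with columns
    ``individual_id, family, sire, dam, population, environment,
    spatial_block, container``.
    """
    if design.n_families == 0:
        raise ValueError("design has no crosses")
    if n_spatial_blocks < 1:
        raise ValueError("n_spatial_blocks must be >= 1")

    if units is not None:
        combos = units[["family", "treatment"]].drop_duplicates()
        combos = combos.rename(columns={"treatment": "environment"})
    else:
        if environments is None:
            environments = default_environments(2)
        combos = pd.DataFrame(
            [
                {"family": f, "environment": e}
                for e in environments
                for f in design.crosses["family"]
            ]
        )
    info = design.crosses.set_index("family")
    combos = combos[combos["family"].isin(info.index)].reset_index(drop=True)

    avail = None
    if availability is not None:
        avail = availability.set_index(["family", "environment"])["n_available"]

    rng = np.random.default_rng(seed)
    rows = []
    for env, env_combos in combos.groupby("environment", sort=True):
        fams = env_combos["family"].tolist()
        if n_containers_per_block is not None and len(fams) > n_containers_per_block:
            raise ValueError(
                f"{len(fams)} families exceed {n_containers_per_block} "
                f"containers per spatial block in environment {env}"
            )
        # which blocks each family fills (all of them unless capped)
        fam_blocks: dict[str, list[int]] = {}
        for f in fams:
            n_avail = n_spatial_blocks
            if avail is not None and (f, env) in avail.index:
                n_avail = min(n_avail, int(avail.loc[(f, env)]))
            chosen = rng.permutation(n_spatial_blocks)[:n_avail] + 1
            fam_blocks[f] = sorted(chosen.tolist())
        for b in range(1, n_spatial_blocks + 1):
            block_fams = [f for f in fams if b in fam_blocks[f]]
            order = rng.permutation(len(block_fams))
            for pos, idx in enumerate(order, start=1):
                f = block_fams[idx]
                cr = info.loc[f]
                rows.append(
                    {
                        "individual_id": f"{f}-{env}-B{b}",
                        "family": f,
                        "sire": cr.sire,
                        "dam": cr.dam,
                        "population": cr.population,
                        "environment": env,
                        "spatial_block": b,
                        "container": pos,
                    }
                )
    placements = pd.DataFrame(rows)
    return placements.sort_values(
        ["environment", "spatial_block", "container"]
    ).reset_index(drop=True)
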