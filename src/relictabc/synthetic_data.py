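"""Synthetic-data generators emulating the study system's structure.

The sequence world mirrors a two-refugium phylogeography sampling design:
24 populations (12 per region), 2-6 diploid individuals each, 27 unlinked
nuclear loci of 154-944 bp, deep inter-region divergence with near-zero
gene flow, and a roughly 2:1 SEA:NEA regional diversity asymmetry.  The
flagship generating history is a vicariance with post-divergence
bottlenecks: divergence at 583 ka, severe NEA shrinkage to ~2,000
diploids around 109 ka with a milder SEA reduction (an equally severe SEA
bottleneck would erase the regional diversity asymmetry the generator
must reproduce; see docs/methods.md), and present sizes of 32,000 (SEA)
and 16,000 (NEA) diploids.

The climate world draws 19 correlated variables from a two-factor latent
model (a precipitation-like and a temperature-like factor) with
region-dependent factor shifts, over both occurrence points and a
lat/lon climate grid, so PCA/IBE/background tests have known ground
truth.  Every generator is seed-deterministic and records its truth.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import locus_mutation_param
from .coalsim import LocusSpec, binary_to_sequences, drop_mutations, locus_rng, simulate_genealogy
from .ibe_niche import ClimateGrid, ClimateOccurrenceTable, MahalanobisEnvelope, SuitabilityRaster
from .scenarios import DEFAULT_GENERATION_TIME, DEFAULT_N_REF, Prior, build_vicariance_scenario, compile_program
from .seqio import LocusAlignment, PhasedMultilocusDataset, SampleMap, SampleRecord, write_dataset

# per-population diploid sample sizes patterned on the study design
SEA_POP_SIZES = (3, 4, 5, 3, 3, 5, 3, 3, 3, 5, 3, 5)
NEA_POP_SIZES = (3, 3, 3, 5, 3, 3, 3, 5, 6, 3, 6, 2)
NUCLEAR_RATE_PER_YEAR = 4.58e-9


@dataclass
class WorldConfig:
    seed: int = 0
    n_pops_per_region: int = 12
    individuals_sea: tuple[int, ...] = SEA_POP_SIZES
    individuals_nea: tuple[int, ...] = NEA_POP_SIZES
    n_loci: int = 27
    locus_length_range: tuple[int, int] = (154, 944)
    scenario_id: str = "VIC_BN_BOTH"
    asymmetry: float = 2.0
    # flagship truth (ka / diploids); NEA bottleneck severe (~2,000), SEA milder
    true_params: dict[str, float] = field(default_factory=lambda: {
        "T": 583.0, "T_SEA": 91.0, "T_NEA": 109.0,
        "N_SEA": 32_000.0, "N_NEA": 16_000.0,
        "N_SEA_b": 8_000.0, "N_NEA_b": 2_000.0,
    })
    n_ref: float = DEFAULT_N_REF
    generation_time: float = DEFAULT_GENERATION_TIME
    mutation_rate_per_year: float = NUCLEAR_RATE_PER_YEAR
    # climate world
    n_occurrences: tuple[int, int] = (65, 35)   # (SEA, NEA)
    effect_precip: float = 2.0                  # regional shift, latent-factor SD units
    effect_temp: float = 2.0
    # fraction of the occurrence-level shift expressed in the background grid:
    # regions share much of their available climate space while the occupied
    # niches diverge further (habitat selection beyond availability)
    background_shift_fraction: float = 0.5
    n_climate_vars: int = 19

    def __post_init__(self) -> None:
        if self.asymmetry < 1:
            raise ValueError("asymmetry must be >= 1")
        if len(self.individuals_sea) != self.n_pops_per_region:
            raise ValueError("individuals_sea length mismatch")
        if len(self.individuals_nea) != self.n_pops_per_region:
            raise ValueError("individuals_nea length mismatch")
        if any(c < 2 or c > 6 for c in self.individuals_sea + self.individuals_nea):
            raise ValueError("2-6 individuals per population")
        lo, hi = self.locus_length_range
        if lo < 1 or hi < lo:
            raise ValueError("bad locus length range")

    def effective_params(self) -> dict[str, float]:
        """Truth with the asymmetry factor applied to the regional sizes."""
        p = dict(self.true_params)
        p["N_NEA"] = p["N_SEA"] / self.asymmetry
        p["N_NEA_b"] = p["N_SEA_b"] / (self.asymmetry ** 2)
        return p


def draw_locus_specs(config: WorldConfig, rng: np.random.Generator) -> list[LocusSpec]:
    lo, hi = config.locus_length_range
    mu_g = config.mutation_rate_per_year * config.generation_time  # per site per generation
    specs = []
    for i in range(config.n_loci):
        length = int(rng.integers(lo, hi + 1))
        theta = 4.0 * config.n_ref * mu_g * length
        specs.append(LocusSpec(f"locus{i + 1:02d}", length, theta))
    return specs


def _sample_map(config: WorldConfig, rng: np.random.Generator) -> tuple[SampleMap, list[str]]:
    """24-population sample map with region-plausible coordinates.

    Returns the map plus the haplotype id list in simulation order
    (all SEA haplotypes first, then NEA)."""
    records: list[SampleRecord] = []
    hap_ids: list[str] = []
    for region, sizes in (("SEA", config.individuals_sea), ("NEA", config.individuals_nea)):
        lat0, lat1 = (25.0, 33.0) if region == "SEA" else (34.0, 41.0)
        lon0, lon1 = (95.0, 120.0) if region == "SEA" else (119.0, 140.0)
        for p, n_ind in enumerate(sizes):
            code = f"{'S' if region == 'SEA' else 'N'}{p + 1:02d}"
            lat = float(rng.uniform(lat0, lat1))
            lon = float(rng.uniform(lon0, lon1))
            for i in range(n_ind):
                ind = f"{code}_i{i + 1}"
                records.append(SampleRecord(ind, code, region, round(lat, 3), round(lon, 3)))
                hap_ids += [f"{ind}_1", f"{ind}_2"]
    return SampleMap(records), hap_ids


def generating_program(config: WorldConfig):
    """Compile the flagship vicariance-with-bottlenecks demography."""
    params = config.effective_params()
    spec = build_vicariance_scenario(
        gene_flow="none", bottlenecks="both",
        priors={k: Prior("point", v) for k, v in params.items()},
        scenario_id=config.scenario_id,
    )
    spec = spec.__class__(**{**spec.__dict__, "n_ref": config.n_ref,
                             "generation_time": config.generation_time})
    return compile_program(spec, params), params


def generate_sequence_world(config: WorldConfig) -> tuple[PhasedMultilocusDataset, dict]:
    """Simulate the study-shaped multilocus dataset plus its truth record."""
    rng = np.random.default_rng([config.seed, 101])
    program, params = generating_program(config)
    loci = draw_locus_specs(config, rng)
    sample_map, hap_ids = _sample_map(config, rng)
    n_sea = 2 * sum(config.individuals_sea)
    n_nea = 2 * sum(config.individuals_nea)
    samples = [n_sea, n_nea]
    alignments = []
    for i, locus in enumerate(loci):
        lrng = np.random.default_rng([config.seed, 202, i])
        g = simulate_genealogy(program, samples, lrng)
        mat = drop_mutations(g, locus, lrng)
        seqs = binary_to_sequences(mat, locus, lrng)
        alignments.append(LocusAlignment(locus.locus_id, dict(zip(hap_ids, seqs))))
    dataset = PhasedMultilocusDataset(alignments, sample_map)
    truth = {
        "scenario_id": config.scenario_id,
        "seed": config.seed,
        "params": params,
        "n_ref": config.n_ref,
        "generation_time": config.generation_time,
        "mutation_rate_per_year": config.mutation_rate_per_year,
        "loci": [{"locus_id": l.locus_id, "length_bp": l.length_bp, "theta": l.theta}
                 for l in loci],
        "samples": {"SEA": n_sea, "NEA": n_nea},
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# climate world

@dataclass
class ClimateWorld:
    occurrences: ClimateOccurrenceTable
    grid: ClimateGrid
    raster_sea: SuitabilityRaster
    raster_nea: SuitabilityRaster
    truth: dict


def _factor_loadings(config: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_vars, 2) loadings: first block precipitation-type, rest temperature."""
    n = config.n_climate_vars
    n_precip = (n + 1) // 2
    load = np.zeros((n, 2))
    load[:n_precip, 0] = rng.uniform(0.7, 1.0, n_precip)
    load[:n_precip, 1] = rng.uniform(-0.15, 0.15, n_precip)
    load[n_precip:, 1] = rng.uniform(0.7, 1.0, n - n_precip)
    load[n_precip:, 0] = rng.uniform(-0.15, 0.15, n - n_precip)
    return load


def generate_climate_world(config: WorldConfig, noise_sd: float = 0.5,
                           grid_shape: tuple[int, int] = (26, 46),
                           cellsize: float = 1.0) -> ClimateWorld:
    """Two-factor latent climate over occurrences and a lat/lon grid.

    Latent factors shift between regions by the configured effect sizes
    (in factor SD units); with zero effects the world is a single climate
    distribution (the null for calibration checks).  Regional suitability
    rasters come from a Mahalanobis envelope of each region's occurrences.
    """
    rng = np.random.default_rng([config.seed, 303])
    load = _factor_loadings(config, rng)
    nrows, ncols = grid_shape
    yll, xll = 20.0, 95.0
    lat_axis = yll + cellsize * (np.arange(nrows)[::-1] + 0.5)  # row 0 = north
    lon_axis = xll + cellsize * (np.arange(ncols) + 0.5)
    lats = np.repeat(lat_axis, ncols)
    lons = np.tile(lon_axis, nrows)
    boundary = 33.0  # SEA south of it, NEA north
    is_nea = lats >= boundary

    def latent(region_flags, rng, fraction=1.0):
        n = len(region_flags)
        f = rng.standard_normal((n, 2))
        f[:, 0] -= fraction * config.effect_precip * region_flags  # NEA drier
        f[:, 1] -= fraction * config.effect_temp * region_flags    # NEA colder
        return f

    grid_factors = latent(is_nea.astype(float), rng,
                          fraction=config.background_shift_fraction)
    grid_climate = grid_factors @ load.T + noise_sd * rng.standard_normal((lats.size, load.shape[0]))
    grid = ClimateGrid(lats, lons, grid_climate, grid_shape, xll, yll, cellsize)

    rows = []
    occ_factors = []
    occ_id = 0
    for region, n_occ in zip(("SEA", "NEA"), config.n_occurrences):
        flags = np.full(n_occ, 1.0 if region == "NEA" else 0.0)
        f = latent(flags, rng)
        occ_factors.append(f)
        clim = f @ load.T + noise_sd * rng.standard_normal((n_occ, load.shape[0]))
        if region == "SEA":
            lat = rng.uniform(21.0, boundary - 1.0, n_occ)
            lon = rng.uniform(96.0, 122.0, n_occ)
        else:
            lat = rng.uniform(boundary + 1.0, 44.0, n_occ)
            lon = rng.uniform(119.0, 140.0, n_occ)
        for i in range(n_occ):
            occ_id += 1
            row = {"occurrence_id": f"occ{occ_id:03d}", "region": region,
                   "latitude": float(lat[i]), "longitude": float(lon[i])}
            row.update({f"bio{j + 1}": float(clim[i, j]) for j in range(load.shape[0])})
            rows.append(row)
    table = ClimateOccurrenceTable(pd.DataFrame(rows))
    raster_sea = grid.suitability_raster(MahalanobisEnvelope().fit(table.climates("SEA")))
    raster_nea = grid.suitability_raster(MahalanobisEnvelope().fit(table.climates("NEA")))
    truth = {
        "seed": config.seed,
        "effect_precip": config.effect_precip,
        "effect_temp": config.effect_temp,
        "background_shift_fraction": config.background_shift_fraction,
        "noise_sd": noise_sd,
        "loadings": load.tolist(),
        "boundary_latitude": boundary,
        # per-occurrence latent factors (precip, temp), rows aligned with table
        "occurrence_factors": np.vstack(occ_factors).tolist(),
    }
    return ClimateWorld(table, grid, raster_sea, raster_nea, truth)


# ---------------------------------------------------------------------------
# fixture bundles

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(out_dir: str | Path, config: WorldConfig) -> dict:
    """Write sequence + climate fixtures with a checksummed JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, seq_truth = generate_sequence_world(config)
    seq_dir = out_dir / "sequences"
    paths = write_dataset(dataset, seq_dir)
    world = generate_climate_world(config)
    occ_path = out_dir / "occurrences.csv"
    world.occurrences.write_csv(occ_path)
    sea_path = out_dir / "suitability_SEA.asc"
    nea_path = out_dir / "suitability_NEA.asc"
    world.raster_sea.write_asc(sea_path)
    world.raster_nea.write_asc(nea_path)
    files = list(paths) + [occ_path, sea_path, nea_path]
    manifest = {
        "seed": config.seed,
        "sequence_truth": seq_truth,
        "climate_truth": world.truth,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def verify_fixture_bundle(out_dir: str | Path) -> bool:
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    return all(_sha256(out_dir / rel) == digest
               for rel, digest in manifest["files"].items())
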