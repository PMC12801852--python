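"""Data model and file I/O for phased multilocus sequence datasets.

A dataset is a collection of per-locus haplotype alignments plus a sample
map assigning each diploid individual to a population and a region (SEA or
NEA).  Haplotype ids follow the convention ``<individual>_1`` /
``<individual>_2``; an individual may be missing from a locus entirely
(tracked in ``missing_loci``), and within-sequence ``N``/``-`` characters
are treated as missing per site by the statistics layer.

On disk: one plain FASTA per locus (file stem = locus id) and a
tab-delimited sample map with header
``individual_id, population, region, latitude, longitude``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGIONS = ("SEA", "NEA")
_HAP_RE = re.compile(r"^(?P<ind>.+)_(?P<phase>[12])$")

# integer coding used by the statistics layer; N and - are missing
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}
MISSING = -1


@dataclass(frozen=True)
class SampleRecord:
    individual_id: str
    population: str
    region: str
    latitude: float
    longitude: float


class SampleMap:
    """Individual -> population -> region mapping with coordinates."""

    def __init__(self, records: list[SampleRecord]):
        ids = [r.individual_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual_id in sample map")
        pop_region: dict[str, str] = {}
        for r in records:
            if r.region not in REGIONS:
                raise ValueError(f"unknown region {r.region!r} (expected one of {REGIONS})")
            if not (-90 <= r.latitude <= 90) or not (-180 <= r.longitude <= 180):
                raise ValueError(f"coordinates out of range for {r.individual_id}")
            prev = pop_region.setdefault(r.population, r.region)
            if prev != r.region:
                raise ValueError(f"population {r.population} mapped to two regions")
        self._records = {r.individual_id: r for r in records}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._records

    def __getitem__(self, individual_id: str) -> SampleRecord:
        return self._records[individual_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleMap) and self._records == other._records

    @property
    def individuals(self) -> list[str]:
        return list(self._records)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self._records.values():
            seen.setdefault(r.population, None)
        return list(seen)

    def region_of(self, population: str) -> str:
        for r in self._records.values():
            if r.population == population:
                return r.region
        raise KeyError(population)

    def individuals_in(self, population: str | None = None, region: str | None = None) -> list[str]:
        out = []
        for r in self._records.values():
            if population is not None and r.population != population:
                continue
            if region is not None and r.region != region:
                continue
            out.append(r.individual_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.individual_id, r.population, r.region, r.latitude, r.longitude)
                for r in self._records.values()
            ],
            columns=["individual_id", "population", "region", "latitude", "longitude"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleMap":
        expected = ["individual_id", "population", "region", "latitude", "longitude"]
        if list(df.columns) != expected:
            raise ValueError(f"sample map columns must be exactly {expected}")
        return cls(
            [
                SampleRecord(str(t.individual_id), str(t.population), str(t.region),
                             float(t.latitude), float(t.longitude))
                for t in df.itertuples(index=False)
            ]
        )


class LocusAlignment:
    """Equal-length haplotype sequences for a single locus."""

    def __init__(self, locus_id: str, haplotypes: dict[str, str]):
        if not haplotypes:
            raise ValueError(f"locus {locus_id}: no haplotypes")
        lengths = {len(s) for s in haplotypes.values()}
        if len(lengths) != 1:
            raise ValueError(f"locus {locus_id}: unequal sequence lengths {sorted(lengths)}")
        (self.length_bp,) = lengths
        if self.length_bp < 1:
            raise ValueError(f"locus {locus_id}: zero-length sequences")
        self.locus_id = locus_id
        self.haplotypes: dict[str, str] = {}
        inds: dict[str, set[str]] = {}
        for hid, seq in haplotypes.items():
            m = _HAP_RE.match(hid)
            if not m:
                raise ValueError(f"haplotype id {hid!r} does not match '<individual>_<1|2>'")
            seq = seq.upper()
            bad = set(seq) - set(_CODE)
            if bad:
                raise ValueError(f"locus {locus_id}: invalid characters {sorted(bad)}")
            self.haplotypes[hid] = seq
            inds.setdefault(m.group("ind"), set()).add(m.group("phase"))
        for ind, phases in inds.items():
            if phases != {"1", "2"}:
                raise ValueError(
                    f"locus {locus_id}: individual {ind} has phases {sorted(phases)}, expected both"
                )
        self._individuals = list(inds)

    @property
    def individuals(self) -> list[str]:
        return list(self._individuals)

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.haplotypes)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def matrix(self, subset: list[str] | None = None) -> np.ndarray:
        """Integer-coded (n_haplotypes, length_bp) matrix; missing = -1."""
        ids = self.haplotype_ids if subset is None else list(subset)
        out = np.empty((len(ids), self.length_bp), dtype=np.int8)
        for i, hid in enumerate(ids):
            out[i] = [_CODE[c] for c in self.haplotypes[hid]]
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LocusAlignment)
            and self.locus_id == other.locus_id
            and self.haplotypes == other.haplotypes
        )


@dataclass
class PhasedMultilocusDataset:
    loci: list[LocusAlignment]
    sample_map: SampleMap
    missing_loci: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_id")
        for loc in self.loci:
            for ind in loc.individuals:
                if ind not in self.sample_map:
                    raise ValueError(f"locus {loc.locus_id}: unknown individual {ind}")

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def locus(self, locus_id: str) -> LocusAlignment:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    def haplotype_ids_for(self, locus: LocusAlignment,
                          population: str | None = None,
                          region: str | None = None) -> list[str]:
        """Haplotype ids at a locus restricted to a population or region."""
        wanted = set(self.sample_map.individuals_in(population=population, region=region))
        return [h for h in locus.haplotype_ids if h.rsplit("_", 1)[0] in wanted]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PhasedMultilocusDataset)
            and self.loci == other.loci
            and self.sample_map == other.sample_map
            and self.missing_loci == other.missing_loci
        )


def read_sample_map(path: str | Path) -> SampleMap:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "population": str, "region": str})
    return SampleMap.from_frame(df)


def write_sample_map(sample_map: SampleMap, path: str | Path) -> None:
    sample_map.to_frame().to_csv(path, sep="\t", index=False)


def read_dataset(fasta_paths: list[str | Path], sample_map_path: str | Path) -> PhasedMultilocusDataset:
    """Read one FASTA per locus plus the sample-map TSV into a validated dataset.

    Loci are ordered as given; record characters are uppercased with 'N'
    and '-' preserved.  Duplicate haplotype ids, unknown individuals and
    unequal within-locus lengths are hard errors.
    """
    sample_map = read_sample_map(sample_map_path)
    loci = []
    missing: set[tuple[str, str]] = set()
    for path in fasta_paths:
        path = Path(path)
        locus_id = path.stem
        haps: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in haps:
                raise ValueError(f"locus {locus_id}: duplicate haplotype id {rec.id}")
            haps[rec.id] = str(rec.seq)
        loc = LocusAlignment(locus_id, haps)
        for ind in loc.individuals:
            if ind not in sample_map:
                raise ValueError(f"locus {locus_id}: haplotype for unknown individual {ind}")
        for ind in sample_map.individuals:
            if ind not in loc.individuals:
                missing.add((ind, locus_id))
        loci.append(loc)
    return PhasedMultilocusDataset(loci, sample_map, missing)


def write_dataset(dataset: PhasedMultilocusDataset, out_dir: str | Path) -> list[Path]:
    """Write one FASTA per locus plus sample_map.tsv; deterministic ordering.

    Records are sorted by individual id then phase.  Returns the written
    paths (FASTAs in locus order, then the TSV).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for loc in dataset.loci:
        path = out_dir / f"{loc.locus_id}.fasta"
        records = [
            SeqRecord(Seq(loc.haplotypes[hid]), id=hid, description="")
            for hid in sorted(loc.haplotype_ids)
        ]
        SeqIO.write(records, str(path), "fasta")
        paths.append(path)
    map_path = out_dir / "sample_map.tsv"
    write_sample_map(dataset.sample_map, map_path)
    paths.append(map_path)
    return paths
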