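import numpy as np
import pytest

from relictabc.seqio import (LocusAlignment, PhasedMultilocusDataset, SampleMap,
                             SampleRecord)


def make_sample_map(n_sea=2, n_nea=2):
    records = []
    for i in range(n_sea):
        records.append(SampleRecord(f"S{i + 1}_i1", f"S{i + 1}", "SEA", 28.0 + i, 100.0 + i))
    for i in range(n_nea):
        records.append(SampleRecord(f"N{i + 1}_i1", f"N{i + 1}", "NEA", 36.0 + i, 128.0 + i))
    return SampleMap(records)


def make_locus(locus_id, seqs_by_individual):
    haps = {}
    for ind, (s1, s2) in seqs_by_individual.items():
        haps[f"{ind}_1"] = s1
        haps[f"{ind}_2"] = s2
    return LocusAlignment(locus_id, haps)


@pytest.fixture
def tiny_dataset():
    """2 loci, 4 individuals (2 SEA + 2 NEA), strong inter-region divergence."""
    l1 = make_locus("locA", {
        "S1_i1": ("AAAAAAAA", "AAAAAAAA"),
        "S2_i1": ("AAAAAAAT", "AAAAAAAA"),
        "N1_i1": ("GGGGAAAA", "GGGGAAAA"),
        "N2_i1": ("GGGGAAAA", "GGGGAAAT"),
    })
    l2 = make_locus("locB", {
        "S1_i1": ("CCCC", "CCCC"),
        "S2_i1": ("CCCC", "CCCT"),
        "N1_i1": ("TTTC", "TTTC"),
        "N2_i1": ("TTTC", "TTTC"),
    })
    return PhasedMultilocusDataset([l1, l2], make_sample_map())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
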