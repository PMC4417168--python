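import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from intragenic_te import annotations, synthetic_data
from intragenic_te.intervals import GeneModel, GenomicInterval, TERecord


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Default synthetic input bundle, seed 1 (shared across tests)."""
    out = tmp_path_factory.mktemp("sim")
    cfg = synthetic_data.SimConfig(seed=1)
    truth = synthetic_data.simulate_all(cfg, out)
    return out, cfg, truth


@pytest.fixture(scope="session")
def reconciled_te_set(sim_dir):
    out, _cfg, _truth = sim_dir
    raw = annotations.read_te_gff3(out / "tes.gff3")
    hits = annotations.parse_repeatmasker_out(out / "rm.out")
    return annotations.build_te_set(raw, hits)


@pytest.fixture(scope="session")
def filtered_genes(sim_dir):
    out, _cfg, _truth = sim_dir
    return annotations.filter_genes(annotations.read_gff3_genes(out / "genes.gff3"))


def make_gene(
    gene_id="G1",
    chrom="Chr1",
    strand="+",
    exons=((1000, 1300), (2000, 2300), (3000, 3300), (4000, 4300)),
    biotype="protein-coding",
):
    intervals = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return GeneModel(
        gene_id=gene_id,
        biotype=biotype,
        interval=GenomicInterval(chrom, intervals[0].start, intervals[-1].end, strand),
        transcripts={f"{gene_id}.1": intervals},
    )


def make_te(te_id="TE1", chrom="Chr1", start=1500, end=1700, family="GypsyF1", superfamily="Gypsy"):
    return TERecord(te_id, family, superfamily, GenomicInterval(chrom, start, end, "."))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
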