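import pytest

from ovilnc.genome import GenomeAnnotation, GenomeInterval, TranscriptModel
from ovilnc.simulate import WorldConfig, generate_world

WORLD_SEED = 11


def make_tx(tid, chrom, blocks, strand="+", gene_id=None, biotype="novel"):
    """Build a TranscriptModel from (start, end) exon blocks."""
    exons = [GenomeInterval(chrom, s, e, strand) for s, e in blocks]
    return TranscriptModel(tid, gene_id or f"{tid}.g", exons, biotype)


def make_annotation(*transcripts):
    ann = GenomeAnnotation()
    for t in transcripts:
        ann.transcripts[t.transcript_id] = t
    ann._invalidate()
    return ann


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """One deterministically generated miniature world shared by the suite."""
    outdir = tmp_path_factory.mktemp("world")
    return generate_world(WorldConfig(seed=WORLD_SEED), outdir)


@pytest.fixture(scope="session")
def pipeline_result(world, tmp_path_factory):
    from ovilnc.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(PipelineConfig(indir=world.outdir, outdir=outdir))
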