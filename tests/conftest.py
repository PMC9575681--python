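import numpy as np
import pytest

from markovfill.pipeline import RunConfig, run_pipeline
from markovfill.sequence_io import ScaffoldRecord, write_fasta
from markovfill.synthetic import (
    SimulationConfig,
    make_gapped_scaffold,
    simulate_genome,
    simulate_long_reads,
)


def _write_inputs(tmpdir, genome, scaffold, reads):
    scaffold_path = tmpdir / "scaffold.fasta"
    reads_path = tmpdir / "reads.fasta"
    write_fasta([scaffold], scaffold_path)
    write_fasta([ScaffoldRecord(r.id, r.sequence) for r in reads], reads_path)
    return scaffold_path, reads_path


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Small error-free simulation: 12 kb genome, five 40-120 base gaps."""
    tmpdir = tmp_path_factory.mktemp("small_sim")
    config = SimulationConfig(
        genome_length=12_000,
        repeat_spec=(),
        gap_spec=((5, 40, 120),),
        read_length_mean=800,
        coverage=12.0,
        error_rate=0.0,
        seed=7,
    )
    genome = simulate_genome(config)
    scaffold, truth = make_gapped_scaffold(genome, config.gap_spec, seed=config.seed + 7)
    reads = simulate_long_reads(genome, config)
    scaffold_path, reads_path = _write_inputs(tmpdir, genome, scaffold, reads)
    return {
        "config": config,
        "genome": genome,
        "scaffold": scaffold,
        "truth": truth,
        "reads": reads,
        "scaffold_path": scaffold_path,
        "reads_path": reads_path,
        "tmpdir": tmpdir,
    }


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Pipeline output on the small simulation."""
    out_dir = small_sim["tmpdir"] / "run"
    config = RunConfig(
        scaffolds=str(small_sim["scaffold_path"]),
        reads=str(small_sim["reads_path"]),
        out_dir=str(out_dir),
        seed=11,
    )
    report = run_pipeline(config)
    return {"report": report, "out_dir": out_dir, "config": config, **small_sim}


@pytest.fixture(scope="session")
def study_sim(tmp_path_factory):
    """The reference study conditions: 50 kb genome, repeat x5 at 2%
    divergence, twenty 50-300 base gaps, 2 kb reads at 15x, no error."""
    tmpdir = tmp_path_factory.mktemp("study_sim")
    config = SimulationConfig(seed=42)
    genome = simulate_genome(config)
    scaffold, truth = make_gapped_scaffold(genome, config.gap_spec, seed=config.seed + 7)
    reads = simulate_long_reads(genome, config)
    scaffold_path, reads_path = _write_inputs(tmpdir, genome, scaffold, reads)
    return {
        "config": config,
        "genome": genome,
        "scaffold": scaffold,
        "truth": truth,
        "reads": reads,
        "scaffold_path": scaffold_path,
        "reads_path": reads_path,
        "tmpdir": tmpdir,
    }


@pytest.fixture(scope="session")
def study_run(study_sim):
    out_dir = study_sim["tmpdir"] / "run"
    config = RunConfig(
        scaffolds=str(study_sim["scaffold_path"]),
        reads=str(study_sim["reads_path"]),
        out_dir=str(out_dir),
        seed=42,
    )
    report = run_pipeline(config)
    return {"report": report, "out_dir": out_dir, "config": config, **study_sim}


@pytest.fixture(scope="session")
def edge_sim(tmp_path_factory):
    """Hand-built edge cases: a 1 bp gap mid-scaffold and a gap at the
    scaffold end (single left flank)."""
    tmpdir = tmp_path_factory.mktemp("edge_sim")
    config = SimulationConfig(
        genome_length=8_000,
        repeat_spec=(),
        gap_spec=(),
        read_length_mean=700,
        coverage=12.0,
        error_rate=0.0,
        seed=19,
    )
    genome = simulate_genome(config)
    ref = genome.sequence
    seq = list(ref)
    seq[4000] = "N"  # 1 bp gap
    tail_start = len(ref) - 90  # gap running to the scaffold end
    seq[tail_start:] = ["N"] * 90
    scaffold = ScaffoldRecord("edge_scaffold", "".join(seq))
    truth = {
        "edge_scaffold_gap1": ref[4000:4001],
        "edge_scaffold_gap2": ref[tail_start:],
    }
    reads = simulate_long_reads(genome, config)
    scaffold_path, reads_path = _write_inputs(tmpdir, genome, scaffold, reads)
    return {
        "reference": ref,
        "scaffold": scaffold,
        "truth": truth,
        "tail_start": tail_start,
        "scaffold_path": scaffold_path,
        "reads_path": reads_path,
        "tmpdir": tmpdir,
    }


@pytest.fixture(scope="session")
def edge_run(edge_sim):
    out_dir = edge_sim["tmpdir"] / "run"
    config = RunConfig(
        scaffolds=str(edge_sim["scaffold_path"]),
        reads=str(edge_sim["reads_path"]),
        out_dir=str(out_dir),
        seed=23,
    )
    report = run_pipeline(config)
    return {"report": report, "out_dir": out_dir, "config": config, **edge_sim}
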