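import pytest

from firstintron.pipeline import RunConfig, run_pipeline
from firstintron.simulate import SimBundle, SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> SimBundle:
    """A 150-gene planted bundle with nested genes and alt transcripts."""
    cfg = SimConfig(
        n_genes=150, seed=7, n_overlap_genes=6, alt_transcript_fraction=0.15
    )
    return simulate(cfg, tmp_path_factory.mktemp("sim") / "bundle")


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    cfg = RunConfig(
        gtf=small_bundle.gtf,
        conservation=small_bundle.conservation,
        mask=small_bundle.repeats,
        peaks=small_bundle.peak_files,
        expression=small_bundle.expression,
        outdir=tmp_path_factory.mktemp("run") / "out",
    )
    return cfg, run_pipeline(cfg)


def brute_force_fraction(regions, covered):
    """Per-base oracle: fraction of region bases inside ``covered``."""
    bases = set()
    for iv in regions:
        bases.update(range(iv.start, iv.end))
    if not bases:
        return float("nan")
    cov = set()
    for iv in covered:
        cov.update(range(iv.start, iv.end))
    return len(bases & cov) / len(bases)
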