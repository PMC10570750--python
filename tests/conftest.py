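import pytest

from isletomics.synthdata import (
    TruthConfig,
    generate_annotation,
    generate_expression,
    generate_peaks_and_coverage,
)


@pytest.fixture(scope="session")
def noisefree():
    """Noise-free planted dataset (seed 7): truth must be exactly recoverable."""
    cfg = TruthConfig(seed=7, noise_sd=0.0, donor_sd=0.0)
    reference, assembled, genome, truth = generate_annotation(cfg)
    table = generate_expression(truth, cfg)
    peaks, tracks = generate_peaks_and_coverage(truth, cfg)
    return {
        "config": cfg,
        "reference": reference,
        "assembled": assembled,
        "genome": genome,
        "truth": truth,
        "table": table,
        "peaks": peaks,
        "tracks": tracks,
    }


@pytest.fixture(scope="session")
def small_annotation():
    """A small annotated dataset with default noise, for cheap unit tests."""
    cfg = TruthConfig(
        seed=3,
        n_known_genes=10,
        n_novel_per_category={
            "lncRNA_antisense": 2,
            "lncRNA_intergenic": 2,
            "pseudogene_duplication": 2,
            "coding_novel": 1,
            "transcribed_enhancer": 2,
            "unresolved": 2,
        },
        enhancer_state_counts={"active_high": 3, "active_low": 3, "poised": 3},
        chrom_length=500_000,
    )
    reference, assembled, genome, truth = generate_annotation(cfg)
    return cfg, reference, assembled, genome, truth
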