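import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miredit.reference_io import MatureAnnotation, PreMiRNA

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_precursor() -> PreMiRNA:
    """An 80-nt hairpin with 22-nt arms at [2, 23] and [55, 76]."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
    return PreMiRNA(
        name="toy-mir-1",
        sequence=seq,
        chrom="chrT",
        start=1001,
        end=1080,
        strand="+",
        matures=(
            MatureAnnotation(name="toy-mir-1-5p", start=2, end=23, arm="5p"),
            MatureAnnotation(name="toy-mir-1-3p", start=55, end=76, arm="3p"),
        ),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study, simulated once per session."""
    from miredit import synthetic_data as sd

    return sd.simulate(sd.default_config(seed=7))


@pytest.fixture(scope="session")
def default_cohort_results(default_cohort):
    """Full pipeline output (profiles + matrix) on the default cohort."""
    from miredit.pipeline import run_cohort
    from miredit.preprocess import RawRead

    cells = [
        (
            c.sample_id,
            c.cell_type,
            [
                RawRead(
                    id=f"r{i}",
                    sequence=s,
                    qualities=tuple(ord(ch) - 33 for ch in q),
                )
                for i, (s, q) in enumerate(c.reads)
            ],
        )
        for c in default_cohort.cells
    ]
    return run_cohort(
        cells,
        default_cohort.reference.precursors,
        default_cohort.reference.snp_records,
    )
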