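import numpy as np
import pytest

from csmfr.core import AnnotationTrack, GenomeSpec, Mutation
from csmfr.filtering import FilterConfig


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSpec:
    return GenomeSpec([("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000)])


def make_mutation(**overrides) -> Mutation:
    """A call that passes every filter criterion unless overridden."""
    fields = dict(
        sample_id="S1",
        group="YC",
        chrom="chr1",
        pos=100_000,
        ref="A",
        alt="T",
        depth=40,
        alt_reads=8,
        filter_flag="PASS",
        popmax_af=None,
        cadd_phred=5.0,
        fathmm_class="nondamaging",
        cohort_site_count=1,
    )
    fields.update(overrides)
    return Mutation(**fields)


@pytest.fixture(scope="session")
def superdups_track() -> AnnotationTrack:
    return AnnotationTrack("superdups", [("chr1", 10_000, 20_000)])


@pytest.fixture(scope="session")
def filter_config(superdups_track) -> FilterConfig:
    return FilterConfig(superdups=superdups_track)


@pytest.fixture(scope="session")
def eight_violations_fixture(superdups_track):
    """12 calls: one violating each of the 8 criteria (all else passing),
    plus 4 clean calls. Positions avoid the SuperDups interval except the
    criterion-3 record."""
    violations = [
        make_mutation(pos=101_000, filter_flag="germline"),
        make_mutation(pos=102_000, chrom="chrY"),
        make_mutation(pos=15_000),  # inside superdups chr1:10000-20000
        make_mutation(pos=104_000, depth=40, alt_reads=20),  # vaf = 0.5
        make_mutation(pos=105_000, depth=19, alt_reads=5),
        make_mutation(pos=106_000, depth=40, alt_reads=2),
        make_mutation(pos=107_000, popmax_af=0.02),
        make_mutation(pos=108_000, cohort_site_count=2),
    ]
    clean = [make_mutation(pos=200_000 + 10_000 * i, sample_id=f"S{i}") for i in range(4)]
    return violations + clean


def random_mutations(rng: np.random.Generator, n: int, chrom_length: int = 1_000_000):
    """Calls with randomised filter-relevant fields for property tests."""
    out = []
    for i in range(n):
        depth = int(rng.integers(5, 200))
        alt = int(rng.integers(0, depth + 1))
        out.append(
            make_mutation(
                sample_id=f"S{rng.integers(0, 20)}",
                group=str(rng.choice(["CEN", "YC"])),
                chrom=str(rng.choice(["chr1", "chr2", "chrY"])),
                pos=int(rng.integers(1, chrom_length)),
                depth=depth,
                alt_reads=alt,
                filter_flag=str(rng.choice(["PASS", "germline"])),
                popmax_af=None if rng.random() < 0.5 else float(rng.random() * 0.05),
                cohort_site_count=int(rng.integers(1, 4)),
            )
        )
    return out
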