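"""Burden, correlation, deleterious-ratio, partition and spectrum statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from csmfr.core import AnnotationTrack
from csmfr.simulate import SimulationConfig, simulate_cohort, write_reference_fasta
from csmfr.stats import (
    SPECTRUM_CLASSES,
    burden_age_correlation,
    burden_summary,
    deleterious_ratio,
    partition_fisher,
    spectrum_class,
    trinucleotide_spectrum,
    wilcoxon_rank_sum,
)

from conftest import make_mutation


def exact_rank_sum_p(x, y):
    """Enumerate every assignment of pooled ranks to group 1."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    n = len(x)
    mean = n * (len(pooled) + 1) / 2
    stats = [
        sum(combo) for combo in itertools.combinations(range(1, len(pooled) + 1), n)
    ]
    extreme = sum(abs(s - mean) >= abs(observed - mean) for s in stats)
    return extreme / len(stats)


def test_wilcoxon_exact_small_sample():
    """{1,2,3} vs {4,5,6}: the rank split is maximally extreme among the
    C(6,3)=20 assignments, giving two-sided p = 2/20 = 0.1."""
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)
    assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_matches_enumeration_oracle():
    rng = np.random.default_rng(19)
    for _ in range(10):
        x = list(rng.choice(1000, size=5, replace=False))
        y = list(rng.choice(2000, size=6, replace=False))
        if set(x) & set(y):
            continue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)


def test_wilcoxon_identical_groups():
    assert wilcoxon_rank_sum([5, 5, 5, 5], [5, 5, 5, 5]) == 1.0


def metadata_frame(pairs):
    return pd.DataFrame(
        [{"sample_id": sid, "group": g, "age": 100.0 if g == "CEN" else 60.0}
         for sid, g in pairs]
    )


def test_burden_summary_includes_zero_burden_samples():
    meta = metadata_frame([("C1", "CEN"), ("C2", "CEN"), ("Y1", "YC"), ("Y2", "YC")])
    muts = [make_mutation(sample_id="C1", pos=100 + i) for i in range(3)]
    summaries, _ = burden_summary(muts, meta)
    assert list(summaries["CEN"].burdens) == [3, 0]
    assert list(summaries["YC"].burdens) == [0, 0]
    assert summaries["CEN"].mean_burden == 1.5


def test_burden_summary_requires_both_groups():
    meta = metadata_frame([("C1", "CEN")])
    with pytest.raises(ValueError, match="no samples"):
        burden_summary([], meta)


def test_burden_means_match_simulated_poisson_rates():
    config = SimulationConfig(
        seed=29, n_cen=80, n_yc=60, burden_mean_cen=50, burden_mean_yc=30,
        n_planted_fr=0, n_planted_cr=0,
    )
    dataset = simulate_cohort(config)
    summaries, p = burden_summary(dataset.mutations, dataset.samples)
    assert summaries["CEN"].mean_burden == pytest.approx(50, rel=0.05)
    assert summaries["YC"].mean_burden == pytest.approx(30, rel=0.05)
    assert p < 1e-6  # a 50-vs-30 burden gap is unambiguous at these sizes


@pytest.mark.parametrize(
    "burdens,ages,expected_r",
    [([1, 2, 3], [10, 20, 30], 1.0), ([3, 2, 1], [1, 2, 3], -1.0)],
)
def test_pearson_perfect_correlation(burdens, ages, expected_r):
    r, p = burden_age_correlation(burdens, ages)
    assert r == pytest.approx(expected_r)
    assert p < 0.05


def test_pearson_zero_variance_raises():
    with pytest.raises(ValueError, match="zero variance"):
        burden_age_correlation([2, 2, 2], [1, 2, 3])


def test_burden_age_r_centred_at_zero_when_independent():
    rs = []
    for seed in range(25):
        rng = np.random.default_rng(seed)
        burdens = rng.poisson(30, size=40)
        ages = rng.normal(60, 8, size=40)
        rs.append(burden_age_correlation(burdens, ages)[0])
    assert abs(np.mean(rs)) < 3 / math.sqrt(40 * 25 / 40)  # ~3 SE of mean r


def test_deleterious_ratio_extremes_and_exclusion():
    meta = metadata_frame([("C1", "CEN"), ("Y1", "YC"), ("Y2", "YC")])
    muts = [
        make_mutation(sample_id="C1", cadd_phred=30.0),
        make_mutation(sample_id="Y1", cadd_phred=40.0, pos=200),
    ]
    with pytest.warns(UserWarning, match="no mutations"):
        means, table, p = deleterious_ratio(muts, meta, predictor="cadd")
    assert means == {"CEN": 1.0, "YC": 1.0}
    assert set(table["sample_id"]) == {"C1", "Y1"}
    assert p == 1.0


def test_deleterious_ratio_recovers_simulated_rates():
    config = SimulationConfig(
        seed=37, n_cen=60, n_yc=60, burden_mean_cen=40, burden_mean_yc=40,
        n_planted_fr=0, n_planted_cr=0,
        deleterious_rate_background=0.1,
    )
    dataset = simulate_cohort(config)
    means, table, _ = deleterious_ratio(dataset.mutations, dataset.samples, "cadd")
    n = table["n_mutations"].sum()
    se = math.sqrt(0.1 * 0.9 / n)
    for g in ("CEN", "YC"):
        assert abs(means[g] - 0.1) < 5 * se + 0.01


def hypergeom_fisher_p(a, b, c, d):
    """Two-sided Fisher p by explicit enumeration of the table family."""
    n1, n2, k = a + b, c + d, a + c
    N = n1 + n2
    denom = math.comb(N, k)
    pmf = {
        x: math.comb(n1, x) * math.comb(n2, k - x) / denom
        for x in range(max(0, k - n2), min(n1, k) + 1)
    }
    cutoff = pmf[a] * (1 + 1e-7)
    return sum(p for p in pmf.values() if p <= cutoff)


def test_partition_fisher_balanced_and_oracle():
    track = AnnotationTrack("cat", [("chr1", 0, 500_000)])
    muts = []
    # CEN: 100 in / 900 out; YC: 200 in / 800 out
    for i in range(1000):
        muts.append(make_mutation(sample_id="C1", group="CEN",
                                  pos=(1000 + i) if i < 100 else (600_000 + i)))
    for i in range(1000):
        muts.append(make_mutation(sample_id="Y1", group="YC",
                                  pos=(1000 + i) if i < 200 else (600_000 + i)))
    table = partition_fisher(muts, track)
    row = table.iloc[0]
    assert (row.cen_in, row.cen_out, row.yc_in, row.yc_out) == (100, 900, 200, 800)
    assert row.fisher_p == pytest.approx(hypergeom_fisher_p(100, 900, 200, 800), abs=1e-12)


def test_partition_fisher_degenerate_table():
    track = AnnotationTrack("cat", [("chr1", 0, 10_000_000)])
    muts = [make_mutation(sample_id=s, group=g, pos=1000 + i)
            for i, (s, g) in enumerate([("C1", "CEN"), ("Y1", "YC")] * 3)]
    table = partition_fisher(muts, track)
    assert table.iloc[0].fisher_p == 1.0


def test_partition_fisher_equal_proportions():
    track = AnnotationTrack("cat", [("chr1", 0, 5000)])
    muts = []
    for g, s in (("CEN", "C1"), ("YC", "Y1")):
        muts += [make_mutation(sample_id=s, group=g, pos=1000) for _ in range(5)]
        muts += [make_mutation(sample_id=s, group=g, pos=9000) for _ in range(5)]
    assert partition_fisher(muts, track).iloc[0].fisher_p == 1.0


# ---------------------------------------------------------------------------
# trinucleotide spectrum


def write_fasta(tmp_path, name, sequences):
    path = tmp_path / name
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n{seq}\n")
    return str(path)


def test_single_context_worked_example(tmp_path):
    fasta = write_fasta(tmp_path, "ref.fa", {"chr1": "GACAG"})
    muts = [make_mutation(chrom="chr1", pos=3, ref="C", alt="A")]
    spectrum = trinucleotide_spectrum(muts, fasta)
    row = spectrum.set_index("context").loc["A[C>A]A"]
    assert row["count"] == 1 and row["fraction"] == 1.0


def test_purine_reference_is_strand_collapsed(tmp_path):
    # G>T at TGT: reverse complement context is ACA, so it lands in A[C>A]A
    fasta = write_fasta(tmp_path, "ref.fa", {"chr1": "TTGTT"})
    muts = [make_mutation(chrom="chr1", pos=3, ref="G", alt="T")]
    spectrum = trinucleotide_spectrum(muts, fasta)
    assert spectrum.set_index("context").loc["A[C>A]A", "count"] == 1
    assert spectrum_class("TGT", "G", "T") == "A[C>A]A"


def test_spectrum_normalisation_and_total(tmp_path):
    rng = np.random.default_rng(41)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    fasta = write_fasta(tmp_path, "ref.fa", {"chr1": seq})
    muts = []
    for _ in range(300):
        pos = int(rng.integers(2, 4999))
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        muts.append(make_mutation(chrom="chr1", pos=pos, ref=ref, alt=str(alt),
                                  sample_id=f"S{_}"))
    spectrum = trinucleotide_spectrum(muts, fasta)
    assert len(spectrum) == 96
    assert list(spectrum["context"]) == list(SPECTRUM_CLASSES)
    assert spectrum["count"].sum() == 300
    assert spectrum["fraction"].sum() == pytest.approx(1.0, abs=1e-12)


def test_spectrum_strand_collapse_involution(tmp_path):
    """Reverse-complementing the reference and alleles leaves the spectrum
    unchanged."""
    rng = np.random.default_rng(43)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    fwd = write_fasta(tmp_path, "fwd.fa", {"chr1": seq})
    rev = write_fasta(tmp_path, "rev.fa", {"chr1": rc})
    muts_fwd, muts_rev = [], []
    for i in range(100):
        pos = int(rng.integers(2, 1999))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        muts_fwd.append(make_mutation(chrom="chr1", pos=pos, ref=ref, alt=alt,
                                      sample_id=f"S{i}"))
        muts_rev.append(make_mutation(chrom="chr1", pos=2000 - pos + 1,
                                      ref=comp[ref], alt=comp[alt], sample_id=f"S{i}"))
    s_fwd = trinucleotide_spectrum(muts_fwd, fwd)
    s_rev = trinucleotide_spectrum(muts_rev, rev)
    assert list(s_fwd["count"]) == list(s_rev["count"])


def test_spectrum_reference_mismatch_raises(tmp_path):
    fasta = write_fasta(tmp_path, "ref.fa", {"chr1": "AAAAA"})
    muts = [make_mutation(chrom="chr1", pos=3, ref="C", alt="T")]
    with pytest.raises(ValueError, match="mismatch"):
        trinucleotide_spectrum(muts, fasta)


def test_simulated_spectrum_matches_reference_context_frequencies(tmp_path):
    """Uniformly placed mutations on a known reference reproduce, within
    multinomial error, the reference's own context frequencies."""
    from csmfr.core import GenomeSpec

    genome = GenomeSpec([("chr1", 30_000)])
    fasta_path = tmp_path / "toy.fa"
    write_reference_fasta(genome, fasta_path, seed=7)
    config = SimulationConfig(
        genome_spec=genome, seed=47, n_cen=30, n_yc=30,
        burden_mean_cen=30, burden_mean_yc=30,
        n_planted_fr=0, n_planted_cr=0, reference_fasta=str(fasta_path),
    )
    dataset = simulate_cohort(config)
    interior = [m for m in dataset.mutations if 2 <= m.pos <= 29_999]
    spectrum = trinucleotide_spectrum(interior, str(fasta_path))
    # pool over substitution type: fraction per (5', 3') flank pair,
    # e.g. "A[C>A]G" -> flanks ("A", "G")
    by_flanks = {}
    for _, row in spectrum.iterrows():
        key = row["context"][0] + row["context"][6]
        by_flanks[key] = by_flanks.get(key, 0) + row["count"]
    # with a uniform random reference all collapsed contexts are equally
    # likely, so each of the 16 flank pairs should get ~1/16 of mutations
    n = sum(by_flanks.values())
    assert len(by_flanks) == 16
    for key, count in by_flanks.items():
        assert abs(count / n - 1 / 16) < 5 * math.sqrt((1 / 16) * (15 / 16) / n)
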