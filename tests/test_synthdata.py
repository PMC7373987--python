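"""Ground-truthed synthetic runs and read-depth expectations."""

import numpy as np
import pytest

from phaseq import (
    PhiXModel,
    SyntheticRunSpec,
    beta_activities,
    compensatory_pattern_activities,
    demux_and_trim,
    enumerate_genotypes,
    expected_read_depth,
    generate_run,
    quantify,
)
from phaseq import synthetic_library as fixture


def make_spec(template, inserts, layout, **kw):
    defaults = dict(
        template=template,
        inserts=inserts,
        activities=beta_activities(template, seed=77),
        n_reads=2000,
        error_rate=0.0,
        layout=layout,
        seed=5,
    )
    defaults.update(kw)
    return SyntheticRunSpec(**defaults)


class TestGenerateRun:
    def test_all_active_genotypes_recover_w_one(self, reduced_template, inserts, layout):
        acts = dict.fromkeys(enumerate_genotypes(reduced_template), 1.0)
        spec = make_spec(reduced_template, inserts, layout, activities=acts)
        records, _ = generate_run(spec)
        table = quantify(iter(records), inserts, reduced_template)
        for g in table.counts:
            assert table.w(g) == 1.0

    def test_all_inactive_gives_zero_cleaved_reads(self, reduced_template, inserts, layout):
        acts = dict.fromkeys(enumerate_genotypes(reduced_template), 0.0)
        spec = make_spec(reduced_template, inserts, layout, activities=acts)
        _, truth = generate_run(spec)
        assert not truth.reads.cleaved.any()

    def test_identical_seeds_give_byte_identical_fastq(self, reduced_template, inserts,
                                                       layout, tmp_path):
        paths = []
        for name in ("a.fastq", "b.fastq"):
            spec = make_spec(reduced_template, inserts, layout, n_reads=500)
            path = tmp_path / name
            generate_run(spec, fastq_path=path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_truth_matches_emitted_reads(self, reduced_template, inserts, layout):
        spec = make_spec(reduced_template, inserts, layout, n_reads=300)
        records, truth = generate_run(spec)
        assert len(records) == 300
        for (rid, seq, qual), (_, row) in zip(records, truth.reads.iterrows()):
            assert rid == row.read_id
            assert len(seq) == len(qual) == layout.read_length
            idx, _ = demux_and_trim(seq, inserts)
            assert idx == row.insert_id

    def test_phix_reads_are_marked_and_unassignable(self, reduced_template, inserts, layout):
        spec = make_spec(reduced_template, inserts, layout,
                         n_reads=400, phix=PhiXModel(0.5))
        records, truth = generate_run(spec)
        n_phix = int(truth.reads.is_phix.sum())
        assert 0 < n_phix < 400
        table = quantify(iter(records), inserts, reduced_template)
        # count conservation holds with PhiX present
        assert table.assigned + table.unassigned + sum(table.dropped.values()) == 400
        assert table.unassigned >= n_phix * 0.99

    def test_seed_mandatory_and_bad_rates_rejected(self, reduced_template, inserts, layout):
        with pytest.raises(ValueError, match="seed"):
            make_spec(reduced_template, inserts, layout, seed=None)
        with pytest.raises(ValueError, match="error_rate"):
            make_spec(reduced_template, inserts, layout, error_rate=0.5)
        with pytest.raises(ValueError, match="activity"):
            make_spec(reduced_template, inserts, layout,
                      activities={"AA": 1.5})

    def test_pseudoknot_pattern_marks_compensatory_high(self, template):
        acts = compensatory_pattern_activities(template, fixture.REFERENCE_GENOTYPE)
        assert acts["CCCGGG"] == 0.9  # wild type pairs
        assert acts["GCCGGC"] == 0.9  # compensatory G-C swap at the outer pair
        assert acts["GCCGGG"] == 0.05  # single mutation breaks one pair
        assert sum(w == 0.9 for w in acts.values()) == 4 ** 3


class TestEndToEndRecovery:
    def test_w_recovered_within_three_binomial_se(self, reduced_template, inserts, layout):
        spec = make_spec(reduced_template, inserts, layout,
                         n_reads=20_000, seed=31)
        records, truth = generate_run(spec)
        table = quantify(iter(records), inserts, reduced_template)
        checked = 0
        for g, (nc, nu) in table.counts.items():
            n = nc + nu
            if n < 100:
                continue
            w_true = truth.activities[g]
            se = np.sqrt(w_true * (1 - w_true) / n)
            assert abs(table.w(g) - w_true) <= 3 * se + 1e-12
            checked += 1
        assert checked == 16  # every genotype of the reduced library is deep enough

    def test_error_free_demux_is_perfect(self, reduced_template, inserts, layout):
        spec = make_spec(reduced_template, inserts, layout, n_reads=3000, seed=13)
        records, truth = generate_run(spec)
        hits = sum(
            demux_and_trim(seq, inserts)[0] == row.insert_id
            for (rid, seq, q), (_, row) in zip(records, truth.reads.iterrows())
        )
        assert hits == 3000

    def test_substitution_errors_reduce_assignment_but_conserve_counts(
        self, reduced_template, inserts, layout
    ):
        spec = make_spec(reduced_template, inserts, layout,
                         n_reads=2000, error_rate=0.01, seed=17)
        records, _ = generate_run(spec)
        table = quantify(iter(records), inserts, reduced_template)
        assert table.unassigned > 0
        assert table.assigned + table.unassigned + sum(table.dropped.values()) == 2000


class TestExpectedReadDepth:
    def test_mean_depth_closed_form(self):
        mean, _ = expected_read_depth(4096, 4096)
        assert mean == 1.0

    def test_single_genotype_never_misses(self):
        _, p_zero = expected_read_depth(10, 1)
        assert p_zero == 0.0

    def test_zero_read_genotype_count_matches_closed_form(self, reduced_template,
                                                          inserts, layout):
        # simulate uniform sampling and compare the number of unseen
        # genotypes with n_genotypes * (1 - 1/n_genotypes)^n_reads
        rng = np.random.default_rng(2)
        n_genotypes, n_reads, reps = 64, 128, 200
        _, p_zero = expected_read_depth(n_reads, n_genotypes)
        expected = n_genotypes * p_zero
        var_one = p_zero * (1 - p_zero)  # per-genotype Bernoulli variance bound
        observed = [
            n_genotypes - len(np.unique(rng.integers(0, n_genotypes, n_reads)))
            for _ in range(reps)
        ]
        se = np.sqrt(n_genotypes * var_one / reps)
        assert abs(np.mean(observed) - expected) <= 3 * se

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            expected_read_depth(0, 10)
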