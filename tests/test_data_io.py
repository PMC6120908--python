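"""Containers, dialect round-trips, missing-call policy, allele alignment."""

import numpy as np
import pandas as pd
import pytest

import episnp as e
from episnp.data_io import MISSING


def random_dataset(rng, n=20, p=50, missing_rate=0.0, with_er=True):
    dosage = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing_rate:
        mask = rng.random((n, p)) < missing_rate
        dosage[mask] = MISSING
    matrix = e.GenotypeMatrix(
        tuple(f"s{i:03d}" for i in range(n)), tuple(f"rs{j:04d}" for j in range(p)), dosage
    )
    status = rng.integers(0, 2, size=n)
    er = [
        rng.choice(["positive", "negative"]) if (s and with_er) else "unknown"
        for s in status
    ]
    pheno = e.PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": list(matrix.sample_ids),
                "status": status,
                "er_status": er,
                "cohort": ["A" if i % 2 else "B" for i in range(n)],
            }
        )
    )
    return matrix, pheno


class TestGenotypeMatrix:
    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(e.GenotypeError, match="invalid dosage"):
            e.GenotypeMatrix(("a", "b"), ("x",), np.array([[3], [0]]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(e.GenotypeError, match="duplicate"):
            e.GenotypeMatrix(("a", "a"), ("x",), np.zeros((2, 1), dtype=int))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(e.GenotypeError, match="shape"):
            e.GenotypeMatrix(("a",), ("x", "y"), np.zeros((2, 1), dtype=int))

    def test_restrict_and_take_preserve_content(self, small_matrix):
        sub = small_matrix.restrict_snps(["rs3", "rs1"])
        assert sub.snp_ids == ("rs3", "rs1")
        np.testing.assert_array_equal(sub.dosage[:, 0], small_matrix.dosage[:, 3])
        rows = small_matrix.take_samples([2, 0])
        assert rows.sample_ids == ("s2", "s0")


class TestPhenotypeTable:
    def test_control_with_er_status_rejected(self):
        with pytest.raises(e.GenotypeError, match="non-unknown er_status"):
            e.PhenotypeTable(
                pd.DataFrame(
                    {"sample_id": ["a"], "status": [0], "er_status": ["positive"], "cohort": ["A"]}
                )
            )

    def test_for_samples_reorders(self, small_pheno):
        sub = small_pheno.for_samples(["s3", "s0"])
        assert sub.sample_ids == ("s3", "s0")
        assert list(sub.status) == [0, 1]


@pytest.mark.parametrize("dialect", ["csv", "plink_raw"])
def test_write_read_round_trip(tmp_path, dialect):
    """Writing then reading a random 20x50 matrix reproduces it exactly."""
    rng = np.random.default_rng(11)
    # plink_raw cannot carry ER status; use ER-free phenotypes there
    matrix, pheno = random_dataset(rng, missing_rate=0.1, with_er=(dialect == "csv"))
    path = tmp_path / f"data.{dialect}"
    e.write_genotype_table(matrix, pheno, path, dialect=dialect)
    matrix2, pheno2 = e.read_genotype_table(path, dialect=dialect)
    assert matrix2.sample_ids == matrix.sample_ids
    assert matrix2.snp_ids == matrix.snp_ids
    np.testing.assert_array_equal(matrix2.dosage, matrix.dosage)
    pd.testing.assert_frame_equal(pheno2.frame, pheno.frame, check_dtype=False)


def test_csv_missing_token_maps_to_sentinel(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text(
        "sample_id,status,er_status,cohort,snp1,snp2\n"
        "s1,1,unknown,A,0,NA\n"
        "s2,0,unknown,A,2,1\n"
    )
    matrix, _ = e.read_genotype_table(path)
    assert matrix.dosage[0, 1] == MISSING
    assert matrix.dosage[1, 0] == 2


def test_malformed_token_names_location(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text(
        "sample_id,status,er_status,cohort,snp1\ns1,1,unknown,A,7\n"
    )
    with pytest.raises(e.ParseError, match=r"s1.*snp1|snp1.*s1"):
        e.read_genotype_table(path)


def test_empty_matrix_round_trip(tmp_path):
    matrix = e.GenotypeMatrix(("s1",), (), np.zeros((1, 0), dtype=int))
    pheno = e.PhenotypeTable(
        pd.DataFrame({"sample_id": ["s1"], "status": [0], "er_status": ["unknown"], "cohort": ["A"]})
    )
    path = tmp_path / "empty.csv"
    e.write_genotype_table(matrix, pheno, path)
    matrix2, _ = e.read_genotype_table(path)
    assert matrix2.n_snps == 0 and matrix2.sample_ids == ("s1",)


class TestDropMissingSnps:
    def test_drops_exactly_affected_columns(self):
        dosage = np.array([[0, 1, 2], [1, MISSING, 0], [2, 1, 1]])
        matrix = e.GenotypeMatrix(("a", "b", "c"), ("snp1", "snp2", "snp3"), dosage)
        out = e.drop_missing_snps(matrix)
        assert out.snp_ids == ("snp1", "snp3")
        assert out.sample_ids == matrix.sample_ids

    def test_identity_when_complete(self, small_matrix):
        assert e.drop_missing_snps(small_matrix) is small_matrix

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(3)
        matrix, _ = random_dataset(rng, n=30, p=100, missing_rate=0.1)
        out = e.drop_missing_snps(matrix)
        expected = [
            s
            for j, s in enumerate(matrix.snp_ids)
            if all(matrix.dosage[i, j] != MISSING for i in range(matrix.n_samples))
        ]
        assert list(out.snp_ids) == expected
        assert (out.dosage != MISSING).all()

    def test_all_dropped_is_error(self):
        matrix = e.GenotypeMatrix(("a",), ("s1",), np.array([[MISSING]]))
        with pytest.raises(e.GenotypeError, match="no SNPs remain"):
            e.drop_missing_snps(matrix)


class TestAlignment:
    @staticmethod
    def _setup(rng, p=12):
        dosage = rng.integers(0, 3, size=(15, p)).astype(np.int8)
        snp_ids = tuple(f"rs{j}" for j in range(p))
        matrix = e.GenotypeMatrix(tuple(f"s{i}" for i in range(15)), snp_ids, dosage)
        flip = rng.random(p) < 0.5
        anns = {
            s: e.SnpAnnotation(s, "1", j + 1, "A", "G", counted_allele="A")
            for j, s in enumerate(snp_ids)
        }
        weights = e.WeightTable(
            pd.DataFrame(
                {
                    "snp_id": list(snp_ids),
                    "effect_allele": ["G" if f else "A" for f in flip],
                    "odds_ratio": rng.uniform(0.5, 2.0, p),
                }
            )
        )
        return matrix, anns, weights, flip

    def test_identity_when_counted_equals_effect(self, small_matrix):
        anns = {s: e.SnpAnnotation(s, "1", 1, "A", "G", "A") for s in small_matrix.snp_ids}
        weights = e.WeightTable(
            pd.DataFrame(
                {"snp_id": list(small_matrix.snp_ids), "effect_allele": "A", "odds_ratio": 1.5}
            )
        )
        out = e.align_dosages_to_effect_allele(small_matrix, anns, weights)
        np.testing.assert_array_equal(out.matrix.dosage, small_matrix.dosage)
        assert out.flipped_snps == ()

    def test_prs_on_aligned_equals_manual_flip_loop(self):
        rng = np.random.default_rng(21)
        matrix, anns, weights, flip = self._setup(rng)
        out = e.align_dosages_to_effect_allele(matrix, anns, weights)
        scores = e.compute_prs(out.matrix, weights).scores
        beta = weights.beta
        expected = np.zeros(matrix.n_samples)
        for i in range(matrix.n_samples):
            for j, s in enumerate(matrix.snp_ids):
                g = matrix.dosage[i, j]
                if flip[j]:
                    g = 2 - g
                expected[i] += beta[list(weights.snp_ids).index(s)] * g
        np.testing.assert_allclose(scores, expected, atol=1e-12)

    def test_alignment_is_involutive(self):
        rng = np.random.default_rng(22)
        matrix, anns, weights, _ = self._setup(rng)
        once = e.align_dosages_to_effect_allele(matrix, anns, weights)
        # swapping each annotation's counted allele to the effect allele and
        # asking for the original counted allele flips everything back
        anns2 = {}
        weights2_rows = []
        for j, s in enumerate(matrix.snp_ids):
            eff = weights.effect_allele_of(s)
            anns2[s] = e.SnpAnnotation(s, "1", j + 1, "A", "G", counted_allele=eff)
            orig = anns[s].counted_allele
            weights2_rows.append({"snp_id": s, "effect_allele": orig, "odds_ratio": 1.5})
        twice = e.align_dosages_to_effect_allele(
            once.matrix, anns2, e.WeightTable(pd.DataFrame(weights2_rows))
        )
        np.testing.assert_array_equal(twice.matrix.dosage, matrix.dosage)

    def test_unknown_effect_allele_is_error(self, small_matrix):
        anns = {s: e.SnpAnnotation(s, "1", 1, "A", "G", "A") for s in small_matrix.snp_ids}
        weights = e.WeightTable(
            pd.DataFrame({"snp_id": ["rs0"], "effect_allele": ["T"], "odds_ratio": [1.2]})
        )
        with pytest.raises(e.GenotypeError, match="effect allele"):
            e.align_dosages_to_effect_allele(small_matrix, anns, weights)

    def test_absent_weight_snps_reported(self, small_matrix):
        anns = {s: e.SnpAnnotation(s, "1", 1, "A", "G", "A") for s in small_matrix.snp_ids}
        weights = e.WeightTable(
            pd.DataFrame(
                {"snp_id": ["rs0", "rsX"], "effect_allele": ["A", "A"], "odds_ratio": [1.2, 1.1]}
            )
        )
        with pytest.warns(UserWarning, match="absent"):
            out = e.align_dosages_to_effect_allele(small_matrix, anns, weights)
        assert out.missing_snps == ("rsX",)
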