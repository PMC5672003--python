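"""Quantification-table parsing, identification filtering, replicate pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secprof.profiles_io import (
    ElutionProfile,
    FractionScheme,
    ProteinRecord,
    SeparationKind,
    filter_identifications,
    pair_replicates,
    read_quant_table,
    write_quant_table,
)


def _profile(scheme, pid, rep, values):
    return ElutionProfile(pid, rep, scheme, np.asarray(values, dtype=float))


class TestFractionScheme:
    def test_requires_contiguous_fractions(self):
        with pytest.raises(ValueError):
            FractionScheme(SeparationKind.SUCROSE, (1, 2, 4))

    def test_requires_three_fractions(self):
        with pytest.raises(ValueError):
            FractionScheme(SeparationKind.SUCROSE, (1, 2))

    def test_void_must_be_inside(self):
        with pytest.raises(ValueError):
            FractionScheme(SeparationKind.SEC_SUPERDEX, (1, 2, 3), void_fraction=9)


class TestReadWrite:
    def test_round_trip_preserves_intensities_exactly(self, sec_scheme, tmp_path):
        rng = np.random.default_rng(0)
        profiles = [
            _profile(sec_scheme, f"AT{i}G{i:05d}", rep, rng.lognormal(14, 2, 24))
            for i in range(5)
            for rep in ("bio1", "bio2")
        ]
        records = {p.protein_id: ProteinRecord(p.protein_id, 3, 12.0) for p in profiles}
        path = tmp_path / "quant.tsv"
        write_quant_table(profiles, records, path)
        back, recs = read_quant_table(path, sec_scheme)
        assert len(back) == len(profiles)
        by_key = {(p.protein_id, p.replicate_id): p for p in back}
        for p in profiles:
            q = by_key[(p.protein_id, p.replicate_id)]
            assert np.array_equal(p.intensities, q.intensities)
        assert recs["AT0G00000"].peptide_count == 3

    def test_specific_row_round_trips(self, tmp_path):
        scheme = FractionScheme(SeparationKind.SEC_SUPERDEX, tuple(range(1, 25)), 2)
        values = [0, 0, 5, 9, 4] + [0] * 19
        write_quant_table([_profile(scheme, "P1", "bio1", values)], None, tmp_path / "q.tsv")
        profiles, _ = read_quant_table(tmp_path / "q.tsv", scheme)
        assert profiles[0].intensities.tolist() == [float(v) for v in values]

    def test_header_only_table_yields_nothing(self, tmp_path):
        scheme = FractionScheme(SeparationKind.SEC_SUPERDEX, (1, 2, 3))
        cols = ["protein_id"] + [f"Intensity bio1 {i}" for i in (1, 2, 3)]
        (tmp_path / "empty.tsv").write_text("\t".join(cols) + "\n")
        profiles, records = read_quant_table(tmp_path / "empty.tsv", scheme)
        assert profiles == [] and records == {}

    def test_blank_cell_becomes_zero(self, tmp_path):
        scheme = FractionScheme(SeparationKind.SEC_SUPERDEX, (1, 2, 3))
        cols = ["protein_id"] + [f"Intensity bio1 {i}" for i in (1, 2, 3)]
        (tmp_path / "q.tsv").write_text(
            "\t".join(cols) + "\nP1\t4.0\t\t2.0\n"
        )
        profiles, _ = read_quant_table(tmp_path / "q.tsv", scheme)
        assert profiles[0].intensities.tolist() == [4.0, 0.0, 2.0]

    def test_missing_fraction_column_is_named_in_error(self, tmp_path):
        scheme = FractionScheme(SeparationKind.SEC_SUPERDEX, (1, 2, 3))
        cols = ["protein_id", "Intensity bio1 1", "Intensity bio1 3"]
        (tmp_path / "q.tsv").write_text("\t".join(cols) + "\nP1\t1\t1\n")
        with pytest.raises(ValueError, match="fraction 2"):
            read_quant_table(tmp_path / "q.tsv", scheme)

    def test_duplicate_protein_id_rejected(self, tmp_path):
        scheme = FractionScheme(SeparationKind.SEC_SUPERDEX, (1, 2, 3))
        cols = ["protein_id"] + [f"Intensity bio1 {i}" for i in (1, 2, 3)]
        body = "P1\t1\t2\t3\nP1\t4\t5\t6\n"
        (tmp_path / "q.tsv").write_text("\t".join(cols) + "\n" + body)
        with pytest.raises(ValueError, match="duplicate"):
            read_quant_table(tmp_path / "q.tsv", scheme)

    def test_comma_separated_dialect_sniffed(self, tmp_path):
        scheme = FractionScheme(SeparationKind.SEC_SUPERDEX, (1, 2, 3))
        cols = ["protein_id"] + [f"Intensity.bio1.{i}" for i in (1, 2, 3)]
        (tmp_path / "q.csv").write_text(",".join(cols) + "\nP1,1,2,3\n")
        profiles, _ = read_quant_table(tmp_path / "q.csv", scheme)
        assert profiles[0].intensities.tolist() == [1.0, 2.0, 3.0]


class TestIdentificationFilter:
    @pytest.mark.parametrize(
        "peptides,score,kept",
        [(1, 4.9, False), (1, 5.0, True), (2, 0.1, True), (1, 50.0, True)],
    )
    def test_single_peptide_score_rule(self, peptides, score, kept):
        records = {"P1": ProteinRecord("P1", peptides, score)}
        assert ("P1" in filter_identifications(records)) is kept

    @given(
        st.lists(
            st.tuples(st.integers(1, 5), st.floats(0, 20, allow_nan=False)),
            max_size=30,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_idempotent_and_never_grows(self, items):
        records = {
            f"P{i}": ProteinRecord(f"P{i}", pep, score)
            for i, (pep, score) in enumerate(items)
        }
        once = filter_identifications(records)
        assert len(once) <= len(records)
        assert filter_identifications(once) == once


class TestPairReplicates:
    def test_intersection_pairing(self, sec_scheme):
        rng = np.random.default_rng(1)
        shared = [f"S{i}" for i in range(3)]
        profiles = []
        for pid in shared:
            for rep in ("bio1", "bio2"):
                profiles.append(_profile(sec_scheme, pid, rep, rng.random(24)))
        profiles.append(_profile(sec_scheme, "U1", "bio1", rng.random(24)))
        profiles.append(_profile(sec_scheme, "U2", "bio2", rng.random(24)))
        pairs, dropped = pair_replicates(profiles)
        assert sorted(p1.protein_id for p1, _ in pairs) == shared
        assert sorted(dropped) == ["U1", "U2"]

    def test_all_zero_profile_counts_as_undetected(self, sec_scheme):
        profiles = [
            _profile(sec_scheme, "P1", "bio1", np.ones(24)),
            _profile(sec_scheme, "P1", "bio2", np.zeros(24)),
        ]
        pairs, dropped = pair_replicates(profiles)
        assert pairs == [] and dropped == ["P1"]

    def test_three_replicates_rejected(self, sec_scheme):
        profiles = [
            _profile(sec_scheme, "P1", rep, np.ones(24))
            for rep in ("bio1", "bio2", "bio3")
        ]
        with pytest.raises(ValueError, match="replicate"):
            pair_replicates(profiles)
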