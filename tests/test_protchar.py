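import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arffam.io import DomainAnnotation
from arffam.protchar import (
    AVERAGE_RESIDUE_MASS,
    ArfClassification,
    MrComposition,
    OrfDivisibilityError,
    PKA_BJELLQVIST,
    ProteinRecord,
    WATER_MASS,
    classify_arf,
    deduced_length,
    extract_mr,
    family_summary,
    isoelectric_point,
    molecular_weight,
    net_charge,
)

AA = sorted(AVERAGE_RESIDUE_MASS)
peptides = st.text(alphabet=AA, min_size=1, max_size=60)


def grid_scan_pi(seq: str, step: float = 1e-5) -> float:
    """Independent oracle: dense pH grid scan for the sign change of the
    Henderson-Hasselbalch net charge."""
    grid = np.arange(0.0, 14.0 + step, step)
    charge = np.array([0.0] * len(grid))
    # same ionizable groups, evaluated directly on the grid
    from arffam.protchar import _ionizable_groups

    for pka, count, sign in _ionizable_groups(seq, PKA_BJELLQVIST):
        if sign > 0:
            charge = charge + count / (1.0 + 10.0 ** (grid - pka))
        else:
            charge = charge - count / (1.0 + 10.0 ** (pka - grid))
    idx = np.searchsorted(-charge, 0.0)  # charge decreasing -> -charge increasing
    idx = min(max(idx, 0), len(grid) - 1)
    return float(grid[idx])


class TestDeducedLength:
    @pytest.mark.parametrize("orf,aa", [(2814, 938), (933, 311), (3, 1)])
    def test_published_convention(self, orf, aa):
        assert deduced_length(orf) == aa

    def test_non_divisible_raises_with_remainder(self):
        with pytest.raises(OrfDivisibilityError) as err:
            deduced_length(1855)
        assert err.value.remainder == 1
        assert deduced_length(1855, round_remainder=True) == 618

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            deduced_length(0)

    @given(st.integers(min_value=1, max_value=10**6))
    @settings(max_examples=50, derandomize=True)
    def test_triples_invert_exactly(self, k):
        assert deduced_length(3 * k) == k


class TestMolecularWeight:
    def test_single_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.005)

    @given(peptides, peptides)
    @settings(max_examples=100, derandomize=True)
    def test_additivity_identity(self, s1, s2):
        lhs = molecular_weight(s1 + s2)
        rhs = molecular_weight(s1) + molecular_weight(s2) - WATER_MASS
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_nonstandard_letter_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            molecular_weight("GGXG")

    def test_agrees_with_biopython(self):
        from Bio.SeqUtils import molecular_weight as bio_mw

        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(AA, size=int(rng.integers(5, 400))))
            assert molecular_weight(seq) == pytest.approx(
                bio_mw(seq, "protein"), rel=1e-4
            )


class TestIsoelectricPoint:
    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            seq = "".join(rng.choice(AA, size=int(rng.integers(5, 120))))
            assert isoelectric_point(seq) == pytest.approx(
                grid_scan_pi(seq), abs=1e-3
            )

    def test_termini_only_peptide(self):
        assert isoelectric_point("AAAAA") == pytest.approx(
            grid_scan_pi("AAAAA"), abs=1e-3
        )

    def test_acidic_below_basic(self):
        assert isoelectric_point("DDDD") < isoelectric_point("KKKK")

    def test_charge_strictly_decreasing(self):
        seq = "MKDECHYARF"
        phs = np.linspace(0.5, 13.5, 40)
        charges = [net_charge(seq, p) for p in phs]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_residue_insertion_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = "".join(rng.choice(AA, size=int(rng.integers(5, 60))))
            k = int(rng.integers(1, len(seq)))
            with_d = seq[:k] + "D" + seq[k:]
            with_k = seq[:k] + "K" + seq[k:]
            base = isoelectric_point(seq)
            assert isoelectric_point(with_d) <= base + 1e-3
            assert isoelectric_point(with_k) >= base - 1e-3

    def test_agrees_with_biopython_inside_its_bracket(self):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(60):
            seq = "".join(rng.choice(AA, size=int(rng.integers(8, 200))))
            mine = isoelectric_point(seq)
            if 4.2 < mine < 11.8:  # Biopython bisects only on [4.05, 12]
                assert mine == pytest.approx(IsoelectricPoint(seq).pi(), abs=0.01)
                checked += 1
        assert checked >= 20


def _protein(seq, dbd=None, ctd=None, pid="p1"):
    domains = []
    if dbd:
        domains.append(DomainAnnotation(pid, "DBD", *dbd))
    if ctd:
        domains.append(DomainAnnotation(pid, "AUX_IAA", *ctd))
    return ProteinRecord(pid, seq, domains=domains)


class TestExtractMr:
    def test_between_dbd_and_ctd(self):
        seq = "A" * 250
        mr = extract_mr(_protein(seq, dbd=(1, 100), ctd=(201, 250)))
        assert (mr.mr_start, mr.mr_end) == (101, 200)

    def test_to_sequence_end_without_ctd(self):
        mr = extract_mr(_protein("A" * 150, dbd=(1, 100)))
        assert (mr.mr_start, mr.mr_end) == (101, 150)

    def test_frequency_hand_count(self):
        seq = "A" * 100 + "QQSSLLPG"
        mr = extract_mr(_protein(seq, dbd=(1, 100)))
        assert mr.freq == {
            "Q": 0.25, "S": 0.25, "L": 0.25, "P": 0.125, "G": 0.125,
        }

    def test_absent_marker_when_dbd_abuts_end(self):
        assert extract_mr(_protein("A" * 100, dbd=(1, 100))) is None

    def test_requires_dbd(self):
        with pytest.raises(ValueError, match="DBD"):
            extract_mr(_protein("A" * 100))


def _mr(freq, pid="p1"):
    rest = 1.0 - sum(freq.values())
    table = dict(freq)
    if rest > 0:
        table["A"] = table.get("A", 0.0) + rest
    return MrComposition(pid, 101, 200, table)


class TestClassifyArf:
    def test_qsl_rich_with_ctd_is_activator(self):
        cls = classify_arf(_mr({"Q": 0.2, "P": 0.03, "G": 0.03}), has_ctd=True)
        assert cls.category == "activator"

    def test_repressor_without_ctd(self):
        cls = classify_arf(_mr({"Q": 0.04, "P": 0.12, "G": 0.12}), has_ctd=False)
        assert cls.category == "repressor_no_CTD"

    def test_close_margin_arithmetic(self):
        # Q=0.10 vs P+G=0.11: repressor by the margin rule
        cls = classify_arf(_mr({"Q": 0.10, "P": 0.06, "G": 0.05}), has_ctd=True)
        assert cls.category == "repressor_with_CTD"
        assert cls.rule_score == pytest.approx(-0.01)

    def test_dbd_only_marker(self):
        assert classify_arf(None, has_ctd=False, protein_id="x").category == "dbd_only"

    def test_override_bypasses_rule(self):
        cls = classify_arf(
            _mr({"Q": 0.3}), has_ctd=True, override="repressor_with_CTD"
        )
        assert cls.category == "repressor_with_CTD"
        assert cls.source == "override"

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            classify_arf(None, has_ctd=False, override="super_activator", protein_id="x")


def _published_classifications():
    from arffam.datasets import papaya_arf_table

    return [
        ArfClassification(r.name, r.category, 0.0, r.has_ctd)
        for r in papaya_arf_table().itertuples(index=False)
    ]


class TestFamilySummary:
    def test_published_family_ratio_and_truncation(self):
        s = family_summary(_published_classifications())
        assert s.n_activators == 4
        assert s.n_repressors == 7
        assert round(s.activator_repressor_ratio, 2) == 0.57
        assert round(s.ctd_truncated_pct, 1) == 36.4

    def test_simple_ratio(self):
        cls = [
            ArfClassification(f"a{i}", "activator", 0.1, True) for i in range(2)
        ] + [
            ArfClassification(f"r{i}", "repressor_with_CTD", -0.1, True)
            for i in range(4)
        ]
        assert family_summary(cls).activator_repressor_ratio == 0.5

    def test_all_activators_undefined_ratio(self):
        cls = [ArfClassification("a", "activator", 0.1, True)]
        assert family_summary(cls).activator_repressor_ratio is None

    def test_permutation_invariance(self):
        cls = _published_classifications()
        fwd = family_summary(cls)
        rev = family_summary(cls[::-1])
        assert fwd == rev

    def test_exclude_policy_changes_denominator(self):
        s = family_summary(_published_classifications(), dbd_only_policy="exclude")
        assert s.n_repressors == 6
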