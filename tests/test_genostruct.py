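import numpy as np
import pandas as pd
import pytest

from xlquant.genostruct import (
    MutationTable,
    RegressedProfile,
    StructuralEvent,
    events_table,
    mutation_overlap,
    regress_out_protein,
    residual_matrix,
    select_events,
)
from xlquant.linkmap import ResiduePairKey
from xlquant.quant_matrix import ResiduePairQuant

SAMPLES = ["s1", "s2", "s3"]


def xl_quant(rows, samples=SAMPLES):
    """rows: {pair string: values}; stage scaled_log2."""
    return ResiduePairQuant(
        data=pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float),
        stage="scaled_log2",
    )


def protein_df(rows, samples=SAMPLES):
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)


class TestRegression:
    def test_perfect_fit_zero_residuals(self):
        x = [0.3, -0.1, 0.8]
        xl = xl_quant({"P1:1--P1:9": x})
        (prof,) = regress_out_protein(xl, protein_df({"P1": x}))
        assert np.allclose(prof.residuals, 0.0, atol=1e-12)

    def test_closed_form_ols_oracle(self):
        xl = xl_quant({"P1:1--P1:9": [1.0, 1.0, 4.0]})
        (prof,) = regress_out_protein(xl, protein_df({"P1": [1.0, 2.0, 3.0]}))
        assert prof.slope == pytest.approx(1.5)
        assert prof.intercept == pytest.approx(-1.0)
        assert prof.residuals == pytest.approx([0.5, -1.0, 0.5])

    def test_affine_shift_absorbed(self):
        x = [0.2, 0.9, -0.4]
        xl = xl_quant({"P1:1--P1:9": [v + 0.7 for v in x]})
        (prof,) = regress_out_protein(xl, protein_df({"P1": x}))
        assert np.allclose(prof.residuals, 0.0, atol=1e-12)

    def test_residuals_zero_sum_and_orthogonal(self):
        rng = np.random.default_rng(6)
        rows = {f"P{i}:1--P{i}:9": rng.normal(size=6).tolist() for i in range(1, 30)}
        prots = {f"P{i}": rng.normal(size=6).tolist() for i in range(1, 30)}
        samples = [f"s{j}" for j in range(6)]
        profiles = regress_out_protein(xl_quant(rows, samples), protein_df(prots, samples))
        assert len(profiles) == 29
        for prof in profiles:
            x = np.array(prots[prof.protein_accession])
            assert abs(prof.residuals.sum()) < 1e-9
            assert abs(np.dot(prof.residuals, x)) < 1e-9

    def test_missing_protein_skipped(self):
        xl = xl_quant({"P1:1--P1:9": [1, 2, 3], "P2:1--P2:9": [1, 2, 3]})
        profiles = regress_out_protein(xl, protein_df({"P1": [1, 2, 3]}))
        assert [p.protein_accession for p in profiles] == ["P1"]

    def test_interlinks_not_regressed(self):
        xl = xl_quant({"P1:1--P2:9": [1, 2, 3]})
        assert regress_out_protein(xl, protein_df({"P1": [1, 2, 3]})) == []

    def test_zero_variance_intercept_only(self):
        xl = xl_quant({"P1:1--P1:9": [1.0, 2.0, 6.0]})
        (prof,) = regress_out_protein(xl, protein_df({"P1": [2.0, 2.0, 2.0]}))
        assert np.isnan(prof.slope)
        assert prof.residuals == pytest.approx([-2.0, -1.0, 3.0])

    def test_wrong_stage_rejected(self):
        q = ResiduePairQuant(
            data=pd.DataFrame([[1.0, 2, 3]], index=["P1:1--P1:9"], columns=SAMPLES),
            stage="raw",
        )
        with pytest.raises(ValueError, match="scaled_log2"):
            regress_out_protein(q, protein_df({"P1": [1, 2, 3]}))


MCM7_MUTATIONS = MutationTable(
    entries=[
        ("MCM7", "LS411N", 284),
        ("MCM7", "SNU1040", 611),
        ("MCM7", "SNU1040", 353),
        ("MCM7", "HCC2998", 231),
    ]
)
MCM7_MAP = {"MCM7": "P33993"}


class TestMutationTable:
    def test_binary_matrix(self):
        mat = MCM7_MUTATIONS.binary_matrix()
        assert mat.loc["MCM7", "SNU1040"] == 1
        assert set(mat.columns) == {"LS411N", "SNU1040", "HCC2998"}
        assert mat.values.sum() == 3  # two SNU1040 entries collapse to one 1

    def test_label_format(self):
        assert MCM7_MUTATIONS.label("MCM7") == (
            "MCM7 | LS411N_284; SNU1040_611; SNU1040_353; HCC2998_231"
        )

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "m.tsv"
        pd.DataFrame(MCM7_MUTATIONS.entries, columns=["gene", "cell_line", "position"]).to_csv(
            path, sep="\t", index=False
        )
        back = MutationTable.from_tsv(path)
        assert back.entries == MCM7_MUTATIONS.entries


class TestMutationOverlap:
    def test_mcm7_145_557_worked_example(self):
        pair = ResiduePairKey.make("P33993", 145, "P33993", 557)
        overlaps = mutation_overlap([pair], MCM7_MUTATIONS, MCM7_MAP)
        cell_lines = {cl for (_, cl) in overlaps}
        assert cell_lines == {"LS411N", "SNU1040", "HCC2998"}
        assert len(cell_lines - {"SNU1040"}) == 2

    def test_mcm7_596_648(self):
        pair = ResiduePairKey.make("P33993", 596, "P33993", 648)
        overlaps = mutation_overlap([pair], MCM7_MUTATIONS, MCM7_MAP)
        assert set(overlaps) == {(pair.as_string(), "SNU1040")}
        assert overlaps[(pair.as_string(), "SNU1040")] == [611]

    def test_boundary_inclusive(self):
        pair = ResiduePairKey.make("P33993", 284, "P33993", 300)
        overlaps = mutation_overlap([pair], MCM7_MUTATIONS, MCM7_MAP)
        assert (pair.as_string(), "LS411N") in overlaps

    def test_unmapped_gene_excluded(self):
        pair = ResiduePairKey.make("X1", 1, "X1", 999)
        overlaps = mutation_overlap([pair], MCM7_MUTATIONS, {})
        assert overlaps == {}


def profile_with(residuals, samples=None, pair="P1:10--P1:90"):
    samples = samples or [f"s{i}" for i in range(len(residuals))]
    return RegressedProfile(
        key=ResiduePairKey.from_string(pair),
        protein_accession="P1",
        samples=samples,
        residuals=np.array(residuals, dtype=float),
        slope=1.0,
        intercept=0.0,
    )


class TestSelectEvents:
    def overlap_for(self, pair, cell):
        return {(pair, cell): [50]}

    def test_passing_event_negative_sign(self):
        prof = profile_with([-0.5, 0.02, -0.03, 0.05, -0.04, 0.0])
        events = select_events([prof], self.overlap_for("P1:10--P1:90", "s0"))
        assert len(events) == 1
        assert events[0].sign == -1
        assert events[0].mutation_positions == [50]

    def test_fails_ratio_cutoff(self):
        prof = profile_with([0.3, 0.0, 0.01, -0.01, 0.0, 0.0])
        assert select_events([prof], self.overlap_for("P1:10--P1:90", "s0")) == []

    def test_fails_sd_cutoff(self):
        prof = profile_with([0.6, -0.5, 0.5, -0.45, 0.55, -0.6])
        events = select_events([prof], self.overlap_for("P1:10--P1:90", "s0"))
        assert events == []  # |0.6| < 2 x SD of that spread

    def test_replicate_averaging(self):
        rep_map = {"s0": "CL1", "s1": "CL1", "s2": "CL2", "s3": "CL3",
                   "s4": "CL4", "s5": "CL5", "s6": "CL6", "s7": "CL7"}
        prof = profile_with([-0.8, -0.7, 0.02, 0.03, -0.02, 0.01, -0.03, 0.02],
                            samples=list(rep_map))
        events = select_events([prof], self.overlap_for("P1:10--P1:90", "CL1"),
                               replicate_map=rep_map)
        assert len(events) == 1
        assert events[0].residual == pytest.approx(-0.75)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        profiles = [
            profile_with(rng.normal(0, 0.3, size=8).tolist(), pair=f"P1:1--P1:{i + 10}")
            for i in range(40)
        ]
        overlaps = {(p.key.as_string(), "s3"): [5] for p in profiles}
        base = len(select_events(profiles, overlaps, ratio_threshold=0.2, sd_multiplier=1.0))
        for rt, sm in [(0.3, 1.0), (0.2, 1.5), (0.5, 2.0)]:
            assert len(select_events(profiles, overlaps, ratio_threshold=rt,
                                     sd_multiplier=sm)) <= base

    def test_no_events_when_xl_equals_protein(self):
        x = np.random.default_rng(1).normal(size=8)
        samples = [f"s{i}" for i in range(8)]
        xl = xl_quant({"P1:10--P1:90": x.tolist()}, samples)
        profiles = regress_out_protein(xl, protein_df({"P1": x.tolist()}, samples))
        overlaps = {("P1:10--P1:90", s): [50] for s in samples}
        assert select_events(profiles, overlaps, ratio_threshold=1e-9,
                             sd_multiplier=0.0) == []

    def test_sign_validation(self):
        with pytest.raises(ValueError, match="sign"):
            StructuralEvent(
                key=ResiduePairKey.from_string("P1:1--P1:2"),
                cell_line="CL1", residual=0.5, sign=0,
            )

    def test_events_table(self):
        prof = profile_with([-0.5, 0.02, -0.03, 0.05, -0.04, 0.0])
        events = select_events([prof], self.overlap_for("P1:10--P1:90", "s0"))
        df = events_table(events)
        assert list(df["sign"]) == [-1]
        assert df.iloc[0]["mutation_positions"] == "50"

    def test_residual_matrix_shape(self):
        profs = [profile_with([0.1, -0.1, 0.0], pair=f"P1:1--P1:{i + 5}") for i in range(3)]
        mat = residual_matrix(profs)
        assert mat.shape == (3, 3)
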