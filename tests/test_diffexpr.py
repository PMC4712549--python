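"""Detection partition, moderated t, BH, on/off, concordance, consensus."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirkd.diffexpr import (ModeratedTTest, OnOffRecord, assemble_candidates,
                            bh_adjust, detection_partition,
                            duplicate_concordance_filter, onoff_lower_limit,
                            replicate_probe_consensus)
from mirkd.io import SampleSheet, ValidationError

from conftest import ct_from_grid


def grid_2v2(kd, ctl, name="a"):
    return pd.DataFrame([list(kd) + list(ctl)], index=[name],
                        columns=["KD1", "KD2", "CTL1", "CTL2"])


U = float("nan")


class TestDetectionPartition:
    @pytest.mark.parametrize("kd,ctl,expect", [
        ((35.0, 36.0), (35.0, 37.0), "excluded"),       # high CT in both arms
        ((30.0, 31.0), (U, U), "onoff"),                # silent controls
        ((34.4, 30.0), (33.0, 31.0), "detected"),       # below-cutoff case
        ((U, U), (U, U), "excluded"),                   # never amplified
        ((30.0, U), (31.0, 31.5), "detected"),          # partial dropout
        ((U, U), (30.0, 35.0), "detected"),             # one ctl above cutoff
    ])
    def test_partition_rules(self, samples_2v2, kd, ctl, expect):
        ct = ct_from_grid(grid_2v2(kd, ctl))
        part = detection_partition(ct, samples_2v2, ct_cutoff=34.5)
        bucket = ("onoff" if "a" in part.onoff
                  else "excluded" if "a" in part.excluded else "detected")
        assert bucket == expect

    def test_onoff_direction(self, samples_2v2):
        ct = ct_from_grid(grid_2v2((30.0, 31.0), (U, U)))
        part = detection_partition(ct, samples_2v2)
        assert part.onoff["a"] == "on_in_knockdown"
        ct = ct_from_grid(grid_2v2((U, U), (30.0, 31.0)))
        assert detection_partition(ct, samples_2v2).onoff["a"] == "off_in_knockdown"


class TestOnOffLowerLimit:
    def test_on_in_knockdown(self, samples_2v2):
        ct = ct_from_grid(grid_2v2((30.0, 30.0), (U, U)))
        rec = onoff_lower_limit(ct, "a", samples_2v2, ct_cutoff=34.5)
        assert rec.log2fc_lower_limit == pytest.approx(4.5)
        assert rec.direction == "on_in_knockdown"
        assert math.isnan(rec.p)

    def test_off_in_knockdown(self, samples_2v2):
        ct = ct_from_grid(grid_2v2((U, U), (28.0, 28.0)))
        rec = onoff_lower_limit(ct, "a", samples_2v2, ct_cutoff=34.5)
        assert rec.log2fc_lower_limit == pytest.approx(-6.5)

    def test_boundary_at_cutoff_gives_zero(self, samples_2v2):
        ct = ct_from_grid(grid_2v2((34.4, 34.4), (U, U)))
        rec = onoff_lower_limit(ct, "a", samples_2v2, ct_cutoff=34.4)
        assert rec.log2fc_lower_limit == pytest.approx(0.0)

    def test_non_candidate_rejected(self, samples_2v2):
        ct = ct_from_grid(grid_2v2((30.0, 30.0), (31.0, 31.0)))
        with pytest.raises(ValidationError, match="on/off"):
            onoff_lower_limit(ct, "a", samples_2v2)


def fit_on(arr, n1, n2, **kw):
    arr = np.asarray(arr, dtype=float)
    cols = [f"K{i}" for i in range(n1)] + [f"C{i}" for i in range(n2)]
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": cols, "group": ["knockdown"] * n1 + ["control"] * n2}))
    x = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])], columns=cols)
    return ModeratedTTest(x, sheet).fit(**kw)


class TestModeratedT:
    def test_flat_feature_has_unit_p(self, rng):
        arr = np.vstack([np.full(6, 5.0), rng.normal(0, 1, 6)])
        res = fit_on(arr, 3, 3)
        assert res.frame.loc["f0", "log2fc"] == 0.0
        assert res.frame.loc["f0", "t_mod"] == 0.0
        assert res.frame.loc["f0", "p"] == pytest.approx(1.0)

    def test_zero_prior_df_reduces_to_classical_t(self, rng):
        arr = rng.normal(0, 1, (200, 7))
        res = fit_on(arr, 3, 4, prior_df=0)
        kd, ctl = arr[:, :3], arr[:, 3:]
        s2 = (kd.var(axis=1, ddof=1) * 2 + ctl.var(axis=1, ddof=1) * 3) / 5
        t_classic = (kd.mean(axis=1) - ctl.mean(axis=1)) / np.sqrt(s2 * (1 / 3 + 1 / 4))
        np.testing.assert_allclose(res.frame["t_mod"], t_classic, rtol=1e-10)

    def test_group_label_swap_negates_lfc_keeps_p(self, rng):
        arr = rng.normal(0, 1, (100, 6))
        res = fit_on(arr, 3, 3)
        swapped = fit_on(arr[:, [3, 4, 5, 0, 1, 2]], 3, 3)
        np.testing.assert_allclose(swapped.frame["log2fc"], -res.frame["log2fc"])
        np.testing.assert_allclose(swapped.frame["p"], res.frame["p"], rtol=1e-12)

    def test_one_vs_one_demands_common_variance(self, rng):
        arr = rng.normal(0, 1, (50, 2))
        with pytest.raises(ValidationError, match="common_variance"):
            fit_on(arr, 1, 1)
        res = fit_on(arr, 1, 1, common_variance=True)
        assert np.all((res.frame["p"] >= 0) & (res.frame["p"] <= 1))

    def test_hyperparameters_shared_and_positive(self, rng):
        arr = rng.normal(0, 1, (300, 4))
        res = fit_on(arr, 2, 2)
        assert res.prior_df > 0 and res.prior_var > 0

    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Independent oracle: limma's lmFit/eBayes on the same matrix."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        arr = rng.normal(8, 1, (60, 6))
        arr[:10, :3] += rng.normal(0, 1.5, (10, 3))
        x = pd.DataFrame(arr, index=[f"f{i}" for i in range(60)],
                         columns=["K1", "K2", "K3", "C1", "C2", "C3"])
        xfile, ofile = tmp_path / "x.tsv", tmp_path / "r.tsv"
        x.to_csv(xfile, sep="\t")
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table("{xfile}", header=TRUE, row.names=1, sep="\t",
                                  check.names=FALSE))
        groups <- factor(rep(c("kd", "ctl"), each=3), levels=c("ctl", "kd"))
        fit <- eBayes(lmFit(x, model.matrix(~groups)))
        out <- data.frame(lfc=fit$coefficients[,2], t=fit$t[,2], p=fit$p.value[,2],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.table(out, "{ofile}", sep="\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(ofile, sep="\t", index_col=0)
        res = fit_on(arr, 3, 3)
        np.testing.assert_allclose(res.frame["log2fc"], ref["lfc"], rtol=1e-8)
        np.testing.assert_allclose(res.frame["t_mod"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res.frame["p"], ref["p"], rtol=1e-8)
        assert res.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res.prior_var == pytest.approx(ref["s02"].iloc[0], rel=1e-6)


class TestBhAdjust:
    def test_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_singleton(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_input_and_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_permutation_invariant(self, rng):
        p = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestDuplicateConcordance:
    def de_frame(self, rows):
        df = pd.DataFrame(rows, columns=["feature_id", "log2fc", "p"])
        df["p_adj"] = df["p"]
        return df.set_index("feature_id")

    def test_concordant_pair_collapsed(self):
        de = self.de_frame([("a1", 0.5, 0.01), ("a2", 0.2, 0.04)])
        out = duplicate_concordance_filter(de, [], {"a1": "m", "a2": "m"})
        assert len(out) == 1
        row = out.iloc[0]
        assert row["feature_id"] == "m"
        assert row["log2fc"] == pytest.approx(0.35)
        assert row["p"] == pytest.approx(0.01)  # smaller member p retained

    def test_discordant_pair_removed(self):
        de = self.de_frame([("a1", 0.5, 0.01), ("a2", -0.3, 0.04)])
        out = duplicate_concordance_filter(de, [], {"a1": "m", "a2": "m"})
        assert out.empty

    def test_singleton_passes_through(self):
        de = self.de_frame([("a1", 0.7, 0.2)])
        out = duplicate_concordance_filter(de, [], {})
        assert out.iloc[0]["feature_id"] == "a1"
        assert out.iloc[0]["log2fc"] == 0.7

    def test_onoff_duplicates_follow_same_rule(self, samples_2v2):
        recs = [OnOffRecord("a1", "on_in_knockdown", 4.0),
                OnOffRecord("a2", "off_in_knockdown", -4.0)]
        out = duplicate_concordance_filter(None, recs, {"a1": "m", "a2": "m"})
        assert out.empty


class TestAssembleCandidates:
    def de_frame(self, ps):
        return pd.DataFrame({
            "log2fc": np.linspace(-1, 1, len(ps)), "p": ps, "p_adj": ps,
        }, index=[f"f{i}" for i in range(len(ps))])

    def test_union_of_significant_and_onoff(self):
        de = self.de_frame([0.01, 0.2, 0.04])
        onoff = [OnOffRecord("x", "on_in_knockdown", 4.5)]
        out = assemble_candidates(de, onoff, alpha=0.05)
        assert set(out["feature_id"]) == {"f0", "f2", "x"}
        assert list(out["log2fc"]) == sorted(out["log2fc"])

    def test_alpha_zero_keeps_only_onoff(self):
        de = self.de_frame([0.0001, 0.001])
        onoff = [OnOffRecord("x", "on_in_knockdown", 4.5)]
        out = assemble_candidates(de, onoff, alpha=0.0)
        assert list(out["feature_id"]) == ["x"]
        assert list(out["status"]) == ["on_off"]

    def test_empty_when_nothing_passes(self):
        out = assemble_candidates(self.de_frame([0.5, 0.9]), [], alpha=0.05)
        assert out.empty


class TestReplicateProbeConsensus:
    def probe_frame(self, rows):
        df = pd.DataFrame(rows, columns=["probe", "log2fc", "p"])
        df["p_adj"] = df["p"]
        return df.set_index("probe")

    def test_all_probes_significant_same_sign_called(self):
        de = self.probe_frame([("p1", 1.0, 0.01), ("p2", 1.2, 0.04)])
        out = replicate_probe_consensus(de, {"p1": "G", "p2": "G"}, alpha=0.05)
        assert bool(out.loc["G", "called"])
        assert out.loc["G", "log2fc"] == pytest.approx(1.1)

    def test_one_insignificant_probe_blocks_call(self):
        de = self.probe_frame([("p1", 1.0, 0.01), ("p2", 1.2, 0.20)])
        out = replicate_probe_consensus(de, {"p1": "G", "p2": "G"})
        assert not bool(out.loc["G", "called"])

    def test_discordant_sign_blocks_call(self):
        de = self.probe_frame([("p1", 1.0, 0.01), ("p2", -0.8, 0.01)])
        out = replicate_probe_consensus(de, {"p1": "G", "p2": "G"})
        assert not bool(out.loc["G", "called"])

    def test_single_probe_gene_called(self):
        de = self.probe_frame([("p1", -0.9, 0.03)])
        out = replicate_probe_consensus(de, {"p1": "G"})
        assert bool(out.loc["G", "called"])

    def test_unmapped_probe_dropped_with_warning(self):
        de = self.probe_frame([("p1", 1.0, 0.01), ("px", 1.0, 0.01)])
        with pytest.warns(UserWarning, match="without a gene mapping"):
            out = replicate_probe_consensus(de, {"p1": "G"})
        assert list(out.index) == ["G"]
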