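"""Simulator ground truth: pangenome structure, expression, read capture."""

import numpy as np
import pandas as pd
import pytest

from tealseq import seq as sequtil
from tealseq import simulate as sim
from tealseq.models import PanelConfig


def _config(seed=3, **kw):
    sp = dict(n_core_genes=10, n_accessory_genes=4)
    sp.update(kw)
    return sim.SimConfig(seed=seed, species=[sim.SpeciesSimConfig("Se", **sp)])


class TestPangenome:
    def test_core_genes_present_in_all_strains(self):
        truth = sim.simulate_pangenome(_config())
        st = truth.species["Se"]
        prev = st.matrix.prevalence()
        core = [g for g in st.matrix.cluster_ids[:10]]
        assert all(prev[g] == st.matrix.n_genomes for g in core)

    def test_zero_snp_rate_makes_strains_identical_over_core(self):
        truth = sim.simulate_pangenome(_config(snp_rate=0.0))
        st = truth.species["Se"]
        for gs in st.strain_gene_seqs:
            for gid, s in gs.items():
                assert s == st.gene_seqs[gid]

    def test_realized_snp_fraction_within_binomial_3sigma(self):
        rate = 0.01
        truth = sim.simulate_pangenome(_config(snp_rate=rate, n_core_genes=40))
        st = truth.species["Se"]
        n_sub = 0
        n_bases = 0
        for gs in st.strain_gene_seqs:
            for gid, s in gs.items():
                ref = st.gene_seqs[gid]
                n_sub += sum(a != b for a, b in zip(s, ref))
                n_bases += len(ref)
        sigma = np.sqrt(n_bases * rate * (1 - rate))
        assert abs(n_sub - n_bases * rate) < 3 * sigma

    def test_cds_intervals_match_gene_sequences(self):
        truth = sim.simulate_pangenome(_config())
        st = truth.species["Se"]
        contig = next(iter(st.reference.contigs.values()))
        for f in st.cds:
            assert contig[f.start : f.end] == st.gene_seqs[f.gene_id]

    def test_byte_identical_for_identical_seed(self):
        a = sim.simulate_pangenome(_config(seed=9))
        b = sim.simulate_pangenome(_config(seed=9))
        assert a.species["Se"].reference.contigs == b.species["Se"].reference.contigs
        assert [s.contigs for s in a.species["Se"].strains] == [
            s.contigs for s in b.species["Se"].strains
        ]
        assert a.host_transcripts == b.host_transcripts


class TestExpression:
    def test_zero_de_fraction_identical_conditions(self):
        cfg = _config()
        cfg.expression.de_fraction = 0.0
        truth = sim.simulate_pangenome(cfg)
        ab = sim.simulate_expression(truth, cfg)
        assert np.array_equal(ab["abund_A"], ab["abund_B"])

    def test_planted_ratio_is_exactly_two_to_log2fc(self):
        cfg = _config()
        truth = sim.simulate_pangenome(cfg)
        ab = sim.simulate_expression(truth, cfg)
        de = ab[ab["de_sign"] != 0]
        assert len(de) == round(0.1 * 14)
        ratios = de["abund_B"] / de["abund_A"]
        assert np.allclose(ratios, np.power(2.0, de["de_sign"] * 3.0))

    def test_lognormal_sample_mean_within_3sigma(self):
        cfg = _config(n_core_genes=5000, n_accessory_genes=0)
        cfg.expression.de_fraction = 0.0
        truth = sim.simulate_pangenome(cfg)
        ab = sim.simulate_expression(truth, cfg)
        mu, sg = cfg.expression.mu_log, cfg.expression.sigma_log
        mean = np.exp(mu + sg**2 / 2)
        sd = np.sqrt((np.exp(sg**2) - 1) * np.exp(2 * mu + sg**2))
        assert abs(ab["abund_A"].mean() - mean) < 3 * sd / np.sqrt(len(ab))


def _reads_setup(seed=5, **readkw):
    cfg = _config(seed=seed, n_core_genes=12, n_accessory_genes=0)
    for k, v in readkw.items():
        setattr(cfg.reads, k, v)
    rng = cfg.rng()
    truth = sim.simulate_pangenome(cfg, rng)
    sim.simulate_expression(truth, cfg, rng)
    panel = sim.uniform_probe_panel(truth.species["Se"], probes_per_gene=3)
    return cfg, truth, panel


class TestCapturedReads:
    def test_conservation_and_origin_partition(self):
        cfg, truth, panel = _reads_setup(n_reads=5000, background_fraction=0.3)
        out = sim.simulate_captured_reads([panel], truth, config=cfg)
        assert len(out["fastq"]) == 5000
        assert len(out["origins"]) == 5000
        assert out["origins"]["read_id"].is_unique
        n_bg = (out["origins"]["origin"] == "background").sum()
        assert n_bg == out["n_background"] == 1500

    def test_clean_reads_overlap_their_source_probe(self):
        cfg, truth, panel = _reads_setup(
            n_reads=2000, error_rate=0.0, background_fraction=0.0, strain_index=0
        )
        cfg.species[0].snp_rate = 0.0
        rng = cfg.rng()
        truth = sim.simulate_pangenome(cfg, rng)
        sim.simulate_expression(truth, cfg, rng)
        panel = sim.uniform_probe_panel(truth.species["Se"], probes_per_gene=3)
        out = sim.simulate_captured_reads([panel], truth, config=cfg)
        spans = {
            p.probe_id: (p.contig_id, p.start, p.end)
            for p in panel.all_probes()
        }
        origin = dict(zip(out["origins"]["read_id"], out["origins"]["origin"]))
        n_checked = 0
        for line in out["sam"]:
            if line.startswith("@"):
                continue
            fields = line.split("\t")
            rid, flag, contig, pos = fields[0], int(fields[1]), fields[2], int(fields[3]) - 1
            end = pos + len(fields[9])
            pc, ps, pe = spans[origin[rid]]
            assert contig == pc and pos < pe and end > ps
            nm = int(fields[11].split(":")[-1])
            assert nm == 0  # zero error, zero SNPs
            n_checked += 1
        assert n_checked == 2000

    def test_expected_counts_track_abundance(self):
        cfg, truth, panel = _reads_setup(n_reads=100_000)
        out = sim.simulate_captured_reads([panel], truth, config=cfg)
        per_gene = (
            out["origins"][out["origins"]["origin"] != "background"]
            .groupby("gene_id")["read_id"].count()
        )
        ab = truth.abundances.set_index("gene_id")["abund_A"]
        shared = per_gene.index.intersection(ab.index)
        r = np.corrcoef(per_gene.loc[shared], ab.loc[shared])[0, 1]
        assert r >= 0.95

    def test_mismatch_model_spe_penalized_mip_tolerant(self):
        """A probe with 4 template mismatches loses ~0.5^4 of its SPE
        efficiency while MIP keeps probes with <=3 mismatches at full
        efficiency and drops them above."""
        cfg, truth, panel = _reads_setup()
        rows = sim._probe_rows(panel)
        templates = {
            cid: seq for cid, seq in truth.species["Se"].reference.contigs.items()
        }
        # plant mismatches into the template under the first two probes
        def plant(template, row, n):
            s = list(template)
            for i in range(n):
                pos = row["start"] + 3 * i
                s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            return "".join(s)

        cid = rows[0]["contig_id"]
        t = plant(templates[cid], rows[0], 4)
        t = plant(t, rows[1], 3)
        templates = {cid: t}

        spe_cfg = sim.ReadSimConfig(method="SPE")
        eff_spe = sim.probe_efficiencies(rows, templates, spe_cfg)
        clean = [i for i in range(2, len(rows))]
        base = np.median(
            [eff_spe[i] for i in clean if abs(rows[i]["tm"] - rows[0]["tm"]) < 0.5]
            or [1 / (1 + np.exp(-spe_cfg.spe_tm_slope * 0))]
        )
        assert eff_spe[0] == pytest.approx(
            (0.5**4) * 1 / (1 + np.exp(-spe_cfg.spe_tm_slope
                                       * (rows[0]["tm"] - np.median([r["tm"] for r in rows])))),
            rel=1e-9,
        )
        mip_cfg = sim.ReadSimConfig(method="MIP")
        eff_mip = sim.probe_efficiencies(rows, templates, mip_cfg)
        assert eff_mip[1] == 1.0  # 3 mismatches tolerated
        assert eff_mip[0] == 0.0  # 4 mismatches -> dropout

    def test_byte_identical_reads_for_identical_seed(self):
        cfg, truth, panel = _reads_setup(n_reads=1000)
        a = sim.simulate_captured_reads([panel], truth, config=cfg)
        b = sim.simulate_captured_reads([panel], truth, config=cfg)
        assert a["fastq"] == b["fastq"]
        assert a["sam"] == b["sam"]
        pd.testing.assert_frame_equal(a["origins"], b["origins"])


class TestCountMatrix:
    def test_shapes_and_depth(self):
        cfg, truth, panel = _reads_setup()
        counts, sheet, gene_map = sim.simulate_count_matrix(
            [panel], truth, n_per_condition=3, depth=20_000, config=cfg
        )
        assert counts.shape == (panel.n_probes, 6)
        assert (counts.sum(axis=0) == 20_000).all()
        assert set(sheet["condition"]) == {"A", "B"}
        assert set(gene_map.index) == set(counts.index)
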