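"""Generative-model tests: reference sampling, strain derivation, droplet
occupancy, amplification models, damage/error bookkeeping."""

import numpy as np
import pytest
from scipy import stats

import dropcirc as dc
from dropcirc._seq import revcomp
from dropcirc.simulate import minor_to_major_map

from conftest import reads_iter


class TestGenerateReference:
    def test_length_alphabet_and_determinism(self):
        ref = dc.generate_reference(100, seed=1)
        assert len(ref) == 100
        assert set(ref) <= set("ACGT")
        assert ref == dc.generate_reference(100, seed=1)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            dc.generate_reference(0, seed=1)

    def test_uniform_base_composition(self):
        # pooled over many seeds each base should appear ~25% of the time
        counts = {b: 0 for b in "ACGT"}
        for seed in range(1000):
            for b in dc.generate_reference(4, seed=seed):
                counts[b] += 1
        total = sum(counts.values())
        for b in "ACGT":
            assert abs(counts[b] / total - 0.25) < 0.05


class TestDeriveStrain:
    def test_snp_count_contract(self):
        ref = dc.generate_reference(1000, seed=2)
        mutated, table = dc.derive_strain(ref, 5, 0, seed=3)
        assert len(table) == 5
        assert table["position"].nunique() == 5
        assert (table["vtype"] == "SNP").all()
        assert (table["ref"] != table["alt"]).all()
        assert len(mutated) == len(ref)  # SNP-only derivation keeps length
        for _, row in table.iterrows():
            assert mutated[row["position"]] == row["alt"]

    def test_identity_when_no_variants(self):
        ref = dc.generate_reference(500, seed=4)
        mutated, table = dc.derive_strain(ref, 0, 0, seed=5)
        assert mutated == ref
        assert len(table) == 0

    def test_full_scale_truth_set(self):
        # 345 SNPs + 6 indels on a 100 kb genome: 351 truth rows
        ref = dc.generate_reference(100_000, seed=6)
        _, table = dc.derive_strain(ref, 345, 6, seed=7)
        assert len(table) == 351
        assert (table["vtype"] == "SNP").sum() == 345

    def test_saturation_guard(self):
        ref = dc.generate_reference(100, seed=8)
        with pytest.raises(ValueError):
            dc.derive_strain(ref, 50, 0, seed=9)

    def test_coordinate_map_roundtrip(self):
        ref = dc.generate_reference(2000, seed=10)
        mutated, table = dc.derive_strain(ref, 10, 8, seed=11)
        m2m = minor_to_major_map(len(ref), table)
        assert len(m2m) == len(mutated)
        # mapped coordinates are sorted and in range
        assert (np.diff(m2m) >= 0).all()
        assert m2m[0] >= 0 and m2m[-1] < len(ref)


def _sim(seed=0, **kw):
    defaults = dict(
        genome_length=5_000, n_snps=10, n_indels=0, n_molecules=2000,
        n_droplets=700, n_read_pairs=50, deamination_rate=0.0,
        polymerase_error_rate=0.0, seq_error_rate=0.0, seed=seed,
    )
    defaults.update(kw)
    cfg = dc.SimConfig(**defaults)
    ref = dc.generate_reference(cfg.genome_length, cfg.seed)
    minor, variants = dc.derive_strain(ref, cfg.n_snps, cfg.n_indels, cfg.seed + 1)
    reads, truth = dc.simulate_run(cfg, ref, minor, variants)
    return cfg, ref, minor, variants, reads, truth


class TestSimConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            dc.SimConfig(fragment_length_range=(80, 200))  # >= read length
        with pytest.raises(ValueError):
            dc.SimConfig(insert_length_range=(200, 700))  # < 2x fragment max
        with pytest.raises(ValueError):
            dc.SimConfig(seq_error_rate=1.5)
        with pytest.raises(ValueError):
            dc.SimConfig(mode="tube")


class TestOccupancy:
    def test_mean_occupancy_matches_loading(self):
        cfg, *_, truth = _sim(seed=1, n_molecules=30_000, n_droplets=10_000)
        occ = truth.molecules.groupby("droplet_id").size()
        mean_occ = occ.sum() / cfg.n_droplets  # empty droplets count as 0
        assert abs(mean_occ - 3.0) <= 0.1

    def test_occupancy_is_poisson(self):
        cfg, *_, truth = _sim(seed=2, n_molecules=30_000, n_droplets=10_000)
        counts = np.bincount(
            truth.molecules.groupby("droplet_id").size().reindex(
                range(cfg.n_droplets), fill_value=0
            )
        )
        lam = cfg.n_molecules / cfg.n_droplets
        k_max = len(counts) - 1
        expected = stats.poisson.pmf(np.arange(k_max + 1), lam) * cfg.n_droplets
        expected[-1] += cfg.n_droplets * stats.poisson.sf(k_max, lam)
        # pool tail bins so every expected count is >= 5
        while expected[-1] < 5 and len(expected) > 2:
            expected[-2] += expected[-1]
            counts[-2] += counts[-1]
            expected, counts = expected[:-1], counts[:-1]
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(expected) - 1)
        assert p > 0.01


class TestAmplification:
    def test_yield_conservation_both_modes(self):
        for mode in ("droplet", "bulk"):
            cfg, *_, truth = _sim(seed=3, mode=mode)
            occupied = truth.molecules["droplet_id"].nunique()
            assert truth.molecules["copies"].sum() == cfg.droplet_yield_copies * occupied

    def test_droplet_mode_less_dispersed_than_bulk(self):
        _, *_, truth_d = _sim(seed=4, mode="droplet")
        _, *_, truth_b = _sim(seed=4, mode="bulk", bulk_dispersion=1.0)
        cv = lambda x: x.std() / x.mean()
        assert cv(truth_d.molecules["copies"]) < cv(truth_b.molecules["copies"])


class TestNoiseBookkeeping:
    def test_no_noise_reads_are_exact_tandem_copies(self):
        _, ref, minor, _, reads, truth = _sim(seed=5, n_read_pairs=100)
        mol = truth.molecules.set_index("molecule_id")
        for i, pair_row in truth.pairs.iterrows():
            row = mol.loc[pair_row["molecule_id"]]
            frag = ref[row.origin_start:row.origin_end]
            if row.strand == "-":
                frag = revcomp(frag)
            if row.strain == "minor":
                continue  # minor fragments checked via pipeline tests
            tandem = frag * 20
            r1 = reads.r1_seq[i]
            assert r1 in tandem
            assert revcomp(reads.r2_seq[i]) in tandem

    def test_deamination_count_matches_binomial(self):
        # ~1e6 C sites on stored strands at rate 0.01
        cfg, ref, minor, _, reads, truth = _sim(
            seed=6, genome_length=50_000, n_molecules=40_000, n_droplets=15_000,
            deamination_rate=0.01, n_read_pairs=10,
        )
        mol = truth.molecules
        n_c = 0
        for _, row in mol.iterrows():
            frag = ref[row.origin_start:row.origin_end]
            if row.strand == "-":
                frag = revcomp(frag)
            n_c += frag.count("C")
        assert n_c > 800_000
        expected = n_c * cfg.deamination_rate
        sd = np.sqrt(n_c * cfg.deamination_rate * (1 - cfg.deamination_rate))
        assert abs(len(truth.damage) - expected) <= 3 * sd

    def test_deamination_is_strand_resolved(self):
        _, ref, *_ , truth = _sim(seed=7, deamination_rate=0.05, n_read_pairs=10)
        mol = truth.molecules.set_index("molecule_id")
        assert len(truth.damage) > 0
        for _, ev in truth.damage.iterrows():
            strand = mol.loc[ev.molecule_id, "strand"]
            if strand == "+":
                assert (ev.ref_from, ev.ref_to) == ("C", "T")
                assert ref[ev.ref_pos] == "C"
            else:
                assert (ev.ref_from, ev.ref_to) == ("G", "A")
                assert ref[ev.ref_pos] == "G"

    def test_polymerase_errors_never_survive_consensus(self):
        # a polymerase error lives in exactly one tandem copy, so unanimity
        # masking removes it: every CS matches its source fragment where unmasked
        from dropcirc._seq import rotate

        _, ref, minor, _, reads, truth = _sim(
            seed=9, polymerase_error_rate=0.005, n_read_pairs=300
        )
        mapped, inter, _ = dc.process_reads(reads_iter(reads), ref)
        mol = truth.molecules.set_index("molecule_id")
        pair_mol = truth.pairs.set_index("pair_id")["molecule_id"]
        assert truth.pairs["n_polymerase_errors"].sum() > 50
        for cs in inter["cs"]:
            row = mol.loc[pair_mol[cs.source_read_id]]
            src = minor if row.strain == "minor" else ref
            frag = src[row.origin_start:row.origin_end]
            if row.strand == "-":
                frag = revcomp(frag)
            assert any(
                all(u in ("N", f) for u, f in zip(cs.unit, rotate(frag, r)))
                for r in range(len(frag))
            )

    def test_deamination_present_in_every_copy(self):
        # all tandem copies of a damaged molecule inherit the damage, so the
        # consensus keeps it (unanimity), visible as the alt in the CS unit
        _, ref, minor, _, reads, truth = _sim(
            seed=8, deamination_rate=0.05, n_read_pairs=200
        )
        mapped, inter, _ = dc.process_reads(reads_iter(reads), ref)
        mol = truth.molecules.set_index("molecule_id")
        pair_mol = truth.pairs.set_index("pair_id")["molecule_id"]
        damage_by_mol = truth.damage.groupby("molecule_id")
        pileup = dc.build_pileup(mapped, ref)
        checked = 0
        for m in mapped:
            mi = pair_mol[m.cs_id]
            if mi not in damage_by_mol.groups or mol.loc[mi, "strain"] == "minor":
                continue
            for _, ev in damage_by_mol.get_group(mi).iterrows():
                site = pileup.get(ev.ref_pos)
                sup = [s for s in site.supporters if s.cs_id == m.cs_id]
                if sup:  # unmasked in this CS -> must carry the damage base
                    assert sup[0].base == ev.ref_to
                    checked += 1
        assert checked > 5
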