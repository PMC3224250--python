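"""Void detector: volumes, classification, lining residues, wall chemistry."""

import numpy as np
import pytest

from coldcore import synthetic, voids
from coldcore.structure_io import Structure
from coldcore.synthetic import _Builder
from coldcore.voids import LiningResidue, VoidError


def dense_ball(radius=6.0, pitch=2.4):
    """A convex solid cluster with no interior space at any sweep probe."""
    b = _Builder()
    ax = np.arange(-radius, radius + pitch, pitch)
    for x in ax:
        for y in ax:
            for z in ax:
                if x * x + y * y + z * z <= radius * radius:
                    b.add_pseudo_atom(np.array([x, y, z]), 1.7, "C")
    return Structure("ball", b.atoms)


class TestDetectVoids:
    def test_sealed_cage_volume_within_five_percent(self):
        spec = synthetic.CageSpec(inner_radius=8.1, seed=1)
        st, analytic = synthetic.make_cage(spec)
        regions = voids.detect_voids(st, 1.4, 0.5, include_pockets=False)
        assert len(regions) == 1 and regions[0].kind == "cavity"
        assert regions[0].volume == pytest.approx(analytic, rel=0.05)

    def test_volume_error_shrinks_with_grid_refinement(self):
        spec = synthetic.CageSpec(inner_radius=6.5, jitter_sd=0.0, seed=2)
        st, analytic = synthetic.make_cage(spec)
        errs = []
        for h in (1.0, 0.5, 0.25):
            regions = voids.detect_voids(st, 1.4, h, include_pockets=False)
            errs.append(abs(sum(v.volume for v in regions) - analytic) / analytic)
        assert errs[2] < errs[0]
        assert errs[2] < 0.02

    def test_open_pocket_and_mouth_count(self):
        st = synthetic.make_open_pocket(
            synthetic.CageSpec(inner_radius=8.0, seed=3), 60
        )
        regions = voids.detect_voids(st, 1.4, 0.5)
        assert [v.kind for v in regions] == ["pocket"]
        assert regions[0].n_mouths == 1

    def test_convex_cluster_has_no_voids(self):
        assert voids.detect_voids(dense_ball(), 1.4, 0.5) == []

    def test_spacing_coarser_than_probe_rejected(self):
        st, _ = synthetic.make_cage(synthetic.CageSpec(inner_radius=7.0, seed=1))
        with pytest.raises(voids.GridError):
            voids.detect_voids(st, 0.6, 0.7)

    def test_waterless_input_required_radii(self):
        st, _ = synthetic.make_cage(synthetic.CageSpec(inner_radius=7.0, seed=1))
        for a in st.atoms:
            a.vdw_radius = None
        with pytest.raises(Exception):
            voids.detect_voids(st, 1.4, 0.5)

    def test_determinism(self):
        st, _ = synthetic.make_cage(synthetic.CageSpec(inner_radius=7.0, seed=9))
        a = voids.detect_voids(st, 1.4, 0.5)
        b = voids.detect_voids(st, 1.4, 0.5)
        assert len(a) == len(b)
        for va, vb in zip(a, b):
            assert va.kind == vb.kind and va.volume == vb.volume
            np.testing.assert_array_equal(va.cells, vb.cells)

    def test_rigid_motion_changes_volume_below_two_percent(self, rng):
        st, _ = synthetic.make_cage(synthetic.CageSpec(inner_radius=7.5, seed=12))
        base = sum(v.volume for v in voids.detect_voids(st, 1.4, 0.5))
        # random rotation + translation
        q = rng.normal(size=(3, 3))
        u, _, vt = np.linalg.svd(q)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        shift = rng.uniform(-3, 3, 3)
        moved = Structure(st.id, [a for a in st.atoms], st.resolution)
        for a in moved.atoms:
            a.coords = rot @ a.coords + shift
        rotated = sum(v.volume for v in voids.detect_voids(moved, 1.4, 0.5))
        assert rotated == pytest.approx(base, rel=0.02)

    def test_partition_is_exhaustive_and_exclusive(self):
        st = synthetic.make_bottleneck_cage(
            synthetic.CageSpec(inner_radius=6.0, seed=5), aperture=1.3
        )
        regions = voids.detect_voids(st, 0.6, 0.5)
        summary = voids.summarize_voids(regions, 0.6)
        assert summary.cavity_volume + summary.pocket_volume == pytest.approx(
            summary.total_void_volume
        )
        seen = set()
        for v in regions:
            cells = {tuple(c) for c in v.cells}
            assert not cells & seen
            seen |= cells

    def test_total_void_volume_monotone_in_probe(self):
        st, _ = synthetic.make_cage(
            synthetic.CageSpec(inner_radius=7.0, seed=8)
        )
        vols = []
        for probe in voids.PROBE_SWEEP:
            regions = voids.detect_voids(st, probe, 0.5)
            vols.append(voids.summarize_voids(regions, probe).total_void_volume)
        assert all(a >= b - 1e-9 for a, b in zip(vols, vols[1:]))


class TestSummarize:
    def _region(self, kind, volume, probe=1.4):
        return voids.VoidRegion(
            id=0, kind=kind, probe_radius=probe, volume=volume,
            n_mouths=0 if kind == "cavity" else 1,
            cells=np.zeros((1, 3), dtype=int),
            grid_origin=np.zeros(3), grid_spacing=0.5,
        )

    def test_two_cavities(self):
        s = voids.summarize_voids(
            [self._region("cavity", 20.0), self._region("cavity", 40.0)], 1.4
        )
        assert (s.cavity_volume, s.n_cavities, s.vol_per_cav) == (60.0, 2, 30.0)

    def test_no_cavities_leaves_average_absent(self):
        s = voids.summarize_voids([self._region("pocket", 15.0)], 1.4)
        assert s.vol_per_cav is None
        assert s.total_void_volume == 15.0

    def test_mixed_probe_radii_rejected(self):
        with pytest.raises(VoidError):
            voids.summarize_voids(
                [self._region("cavity", 10.0, 1.4), self._region("cavity", 10.0, 1.6)],
                1.4,
            )


class TestLining:
    def test_cage_shell_residues_line_the_cavity(self):
        spec = synthetic.CageSpec(inner_radius=6.0, seed=21)
        st, _ = synthetic.make_cage(spec, wall_freqs=synthetic.BASE_WALL_FREQS)
        region = voids.detect_voids(st, 1.4, 0.5, include_pockets=False)[0]
        lining = voids.lining_residues(region, st, 1.4)
        shell_keys = {a.residue_key for a in st.atoms}
        assert {r.key for r in lining} == shell_keys
        assert all(r.side_chain_contact for r in lining)  # shells are CB atoms

    def test_backbone_only_contact_is_flagged_false(self):
        spec = synthetic.CageSpec(inner_radius=6.0, seed=22)
        st, _ = synthetic.make_cage(spec)
        for a in st.atoms:
            a.atom_name = "O"  # backbone carbonyl contact only
        region = voids.detect_voids(st, 1.4, 0.5, include_pockets=False)[0]
        lining = voids.lining_residues(region, st, 1.4)
        assert lining and all(not r.side_chain_contact for r in lining)

    def test_distant_residue_absent(self):
        spec = synthetic.CageSpec(inner_radius=6.0, seed=23)
        st, _ = synthetic.make_cage(spec)
        far = _Builder()
        far.add_pseudo_atom(np.array([40.0, 0, 0]), 1.7, "Z")
        st2 = synthetic.merge_structures(
            [st, Structure("far", far.atoms)], "with_far"
        )
        region = voids.detect_voids(st2, 1.4, 0.5, include_pockets=False)[0]
        keys = {r.key for r in voids.lining_residues(region, st2, 1.4)}
        assert all(k[0] != "Z" for k in keys)


class TestClassifyLining:
    def _res(self, name, side=True):
        return LiningResidue(("A", 1, ""), name, side)

    def test_four_class_arithmetic(self):
        prof = voids.classify_lining(
            [self._res("GLU"), self._res("ASP"), self._res("LEU")]
        )
        assert prof.frequencies["acidic"] == pytest.approx(2 / 3)
        assert prof.frequencies["hydrophobic"] == pytest.approx(1 / 3)

    def test_backbone_contacts_not_counted(self):
        prof = voids.classify_lining([self._res("GLU", side=False)])
        assert sum(prof.counts.values()) == 0
        assert prof.frequencies is None

    def test_tyr_goes_to_polar_and_is_flagged(self):
        prof = voids.classify_lining([self._res("TYR")])
        assert prof.counts["polar"] == 1
        assert prof.n_tyr == 1

    def test_unknown_residue_in_other_bucket(self):
        prof = voids.classify_lining([self._res("XYZ"), self._res("LYS")])
        assert prof.n_other == 1
        assert prof.counts["basic"] == 1
        assert prof.frequencies["basic"] == pytest.approx(1.0)

    def test_acidic_bias_raises_acidic_frequency(self, rng):
        biased_counts, base_counts = [], []
        for seed in range(8):
            spec = synthetic.CageSpec(inner_radius=6.0, seed=seed)
            for freqs, out in (
                (synthetic._biased_freqs(0.2), biased_counts),
                (synthetic.BASE_WALL_FREQS, base_counts),
            ):
                st, _ = synthetic.make_cage(spec, wall_freqs=freqs)
                region = voids.detect_voids(st, 1.4, 0.5, include_pockets=False)[0]
                prof = voids.classify_lining(voids.lining_residues(region, st, 1.4))
                out.append(prof.frequencies["acidic"])
        assert np.mean(biased_counts) > np.mean(base_counts) + 0.1
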