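"""I/O round-trips and validation for VCF genotypes, occurrence tables,
ESRI ASCII raster stacks, and distance-matrix writers."""

import numpy as np
import pytest

from polyrank import formats_io as fio


VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tdip1\ttet1
chr1\t10\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0/0/1
chr1\t20\t.\tC\tT,A\t.\t.\t.\tGT\t./.\t1/1/2/2
chr1\t30\t.\tG\tA\t.\t.\t.\tGT\t0/0\t./././.
"""


@pytest.fixture()
def vcf_file(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestReadVcf:
    def test_dosage_parsing_mixed_ploidy(self, vcf_file):
        g = fio.read_vcf_genotypes(
            vcf_file, {"dip1": "A", "tet1": "B"}, {"dip1": 2, "tet1": 4}
        )
        assert g.sample_ids == ["dip1", "tet1"]
        # diploid 0/1 -> (1, 1); tetraploid 0/0/0/1 -> (3, 1)
        np.testing.assert_array_equal(g.dosages[0, 0, :2], [1, 1])
        np.testing.assert_array_equal(g.dosages[1, 0, :2], [3, 1])
        # multiallelic tetraploid 1/1/2/2 -> (0, 2, 2)
        np.testing.assert_array_equal(g.dosages[1, 1], [0, 2, 2])
        # missing conventions for both ploidies
        assert np.isnan(g.dosages[0, 1]).all()
        assert np.isnan(g.dosages[1, 2]).all()

    def test_arity_mismatch_is_hard_error(self, vcf_file):
        with pytest.raises(ValueError, match="dip1.*chr1:10|chr1:10.*dip1"):
            fio.read_vcf_genotypes(vcf_file, {}, {"dip1": 4, "tet1": 4})

    def test_unknown_sample_errors(self, vcf_file):
        with pytest.raises(ValueError, match="ploidy_map"):
            fio.read_vcf_genotypes(vcf_file, {}, {"dip1": 2})

    def test_roundtrip_reproduces_dosages(self, vcf_file, tmp_path):
        g = fio.read_vcf_genotypes(
            vcf_file, {"dip1": "A", "tet1": "B"}, {"dip1": 2, "tet1": 4}
        )
        out = tmp_path / "rt.vcf"
        fio.write_vcf_genotypes(g, out)
        g2 = fio.read_vcf_genotypes(out, g.taxon_of, g.ploidy_of)
        np.testing.assert_array_equal(
            np.isnan(g.dosages), np.isnan(g2.dosages)
        )
        np.testing.assert_allclose(
            np.nan_to_num(g.dosages), np.nan_to_num(g2.dosages)
        )


class TestOccurrences:
    def test_dedup_and_parse(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("taxon,lon,lat\nA,1.0,2.0\nA,1.0,2.0\nB,3.0,4.0\n")
        occ = fio.read_occurrence_table(p)
        assert len(occ.records) == 2
        assert occ.taxa == ["A", "B"]

    def test_out_of_range_latitude(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("taxon,lon,lat\nA,1.0,95.0\n")
        with pytest.raises(ValueError, match="row 2"):
            fio.read_occurrence_table(p)

    def test_empty_with_header_warns(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("taxon,lon,lat\n")
        with pytest.warns(UserWarning):
            occ = fio.read_occurrence_table(p)
        assert occ.records == []


class TestEnvRasters:
    def _write(self, tmp_path, name, arr, xll, yll, res=0.5):
        p = tmp_path / f"{name}.asc"
        fio.write_esri_ascii(np.asarray(arr, float),
                             (xll, xll + arr.shape[1] * res, yll, yll + arr.shape[0] * res),
                             res, p)
        return p

    def test_identical_grids_stack(self, tmp_path):
        a = np.arange(12.0).reshape(3, 4)
        p1 = self._write(tmp_path, "l1", a, 0.0, 40.0)
        p2 = self._write(tmp_path, "l2", a * 2, 0.0, 40.0)
        stack = fio.read_env_rasters([p1, p2])
        assert stack.shape == (3, 4)
        np.testing.assert_allclose(stack.layers["l1"], a)

    def test_idempotent_reread(self, tmp_path):
        a = np.arange(12.0).reshape(3, 4)
        p1 = self._write(tmp_path, "l1", a, 0.0, 40.0)
        s1 = fio.read_env_rasters([p1])
        p2 = tmp_path / "again.asc"
        fio.write_esri_ascii(s1.layers["l1"], s1.extent, s1.resolution, p2)
        s2 = fio.read_env_rasters([p2])
        np.testing.assert_array_equal(s1.layers["l1"], s2.layers["again"])
        assert s1.extent == s2.extent

    def test_half_overlap_cropped_to_intersection(self, tmp_path):
        # second layer shifted east by 2 cells (of 4): intersection is 2 cols
        a = np.arange(12.0).reshape(3, 4)
        p1 = self._write(tmp_path, "l1", a, 0.0, 40.0)
        p2 = self._write(tmp_path, "l2", a, 1.0, 40.0)
        stack = fio.read_env_rasters([p1, p2])
        assert stack.extent == (1.0, 2.0, 40.0, 41.5)
        assert stack.shape == (3, 2)
        # hand-computed: l1 keeps its last two columns, l2 its first two
        np.testing.assert_allclose(stack.layers["l1"], a[:, 2:])
        np.testing.assert_allclose(stack.layers["l2"], a[:, :2])

    def test_disjoint_extents_error(self, tmp_path):
        a = np.ones((2, 2))
        p1 = self._write(tmp_path, "l1", a, 0.0, 40.0)
        p2 = self._write(tmp_path, "l2", a, 10.0, 40.0)
        with pytest.raises(ValueError, match="disjoint"):
            fio.read_env_rasters([p1, p2])

    def test_cell_of_half_open_convention(self):
        stack = fio.EnvStack(
            layers={"x": np.zeros((2, 2))}, extent=(0.0, 2.0, 0.0, 2.0), resolution=1.0
        )
        assert stack.cell_of(0.0, 1.999999) == (0, 0)  # row 0 = north
        assert stack.cell_of(1.0, 0.5) == (1, 1)


class TestDistanceWriters:
    def test_nexus_roundtrip_and_quoting(self, tmp_path):
        labels = ["L. vulgare", "plain"]
        D = np.array([[0.0, 0.5], [0.5, 0.0]])
        p = tmp_path / "d.nex"
        fio.write_distance_nexus(labels, D, p)
        text = p.read_text()
        assert "NTAX=2" in text and "'L. vulgare'" in text and "0.5" in text
        labels2, D2 = fio.read_distance_nexus(p)
        assert labels2 == labels
        np.testing.assert_allclose(D2, D, atol=1e-9)

    def test_asymmetric_matrix_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="asymmetric"):
            fio.write_distance_nexus(["a", "b"], np.array([[0, 1], [2, 0.0]]),
                                     tmp_path / "bad.nex")

    def test_phylip_square(self, tmp_path):
        p = tmp_path / "d.phy"
        fio.write_distance_phylip(["a b", "c"], np.array([[0, 1.25], [1.25, 0.0]]), p)
        lines = p.read_text().splitlines()
        assert lines[0].strip() == "2"
        assert lines[1].startswith("a_b")


class TestLeafAnnotationIO:
    def test_json_roundtrip(self, tmp_path, straight_leaves):
        annots, _, _ = straight_leaves
        p = tmp_path / "leaves.json"
        fio.write_leaf_annotations_json(annots, p)
        back = fio.read_leaf_annotations_json(p)
        assert len(back) == len(annots)
        np.testing.assert_allclose(back[0].outline, annots[0].outline)
        np.testing.assert_allclose(back[0].midvein, annots[0].midvein)

    def test_cvat_xml(self, tmp_path):
        xml = """<annotations>
          <image id="0" name="sheet1" width="100" height="80">
            <polygon label="leaf" points="10,10;90,10;90,70;10,70"/>
            <polyline label="vein" points="10,40;90,40"/>
          </image>
        </annotations>"""
        p = tmp_path / "cvat.xml"
        p.write_text(xml)
        annots = fio.read_leaf_annotations_cvat(p)
        assert len(annots) == 1
        assert annots[0].image_size == (80, 100)
        assert annots[0].outline.shape == (4, 2)

    def test_midvein_needs_two_vertices(self):
        with pytest.raises(ValueError, match="midvein"):
            fio.LeafAnnotation("x", np.array([[0, 0], [1, 0], [1, 1]]),
                               np.array([[0.5, 0.5]]), (2, 2))
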