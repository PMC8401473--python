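import numpy as np
import pytest

from breastfem.volume import LabelMap, Label
from breastfem import meshing
from breastfem.meshing import (voxel_to_hex_mesh, add_skin_layer,
                               mesh_convergence_check, write_vtk,
                               TISSUE_ADIPOSE, TISSUE_FIBROGLANDULAR,
                               TISSUE_SKIN)
from breastfem.materials import MaterialParams
from breastfem import fem

from .conftest import cube_labels, hemisphere_labels


class TestVoxelToHexMesh:
    def test_cube_element_and_node_counts(self):
        # 10 mm cube of 2 mm voxels meshed at 2 mm: 5^3 elements, 6^3 nodes
        mesh = voxel_to_hex_mesh(cube_labels(n_vox=5, spacing=2.0), 2.0)
        assert mesh.n_elements == 125
        assert mesh.n_nodes == 216

    def test_single_voxel_single_element(self):
        mesh = voxel_to_hex_mesh(cube_labels(n_vox=1, spacing=2.0), 2.0)
        assert mesh.n_elements == 1
        assert mesh.n_nodes == 8
        assert mesh.jacobians_positive()

    def test_element_size_below_voxel_spacing_rejected(self):
        with pytest.raises(ValueError):
            voxel_to_hex_mesh(cube_labels(), 1.0)

    def test_empty_labels_rejected(self):
        lab = LabelMap(data=np.zeros((4, 4, 4), dtype=np.int64),
                       spacing=[2, 2, 2])
        with pytest.raises(ValueError):
            voxel_to_hex_mesh(lab, 2.0)

    def test_mesh_volume_matches_labeled_volume(self):
        # checked at the default phantom scale; coarser-than-voxel meshing
        # of tiny volumes has proportionally larger boundary error
        labels = hemisphere_labels(radius=50.0, spacing=2.0)
        mesh = voxel_to_hex_mesh(labels, 4.0)
        vox_vol = labels.breast_mask().sum() * np.prod(labels.spacing)
        assert abs(mesh.element_volumes().sum() - vox_vol) <= 0.03 * vox_vol

    def test_majority_tissue_tagging(self):
        lab = cube_labels(n_vox=4, spacing=2.0)
        # fill one 4 mm corner cell (2x2x2 voxels) with gland
        d = lab.data
        i = np.argwhere(d == Label.ADIPOSE).min(axis=0)
        d[i[0]:i[0] + 2, i[1]:i[1] + 2, i[2]:i[2] + 2] = Label.FIBROGLANDULAR
        mesh = voxel_to_hex_mesh(lab, 4.0)
        assert (mesh.element_tissue == TISSUE_FIBROGLANDULAR).sum() == 1
        assert (mesh.element_tissue == TISSUE_ADIPOSE).sum() == 7

    def test_gland_elements_lie_in_dilated_gland_mask(self, small_case):
        from scipy.ndimage import binary_dilation
        labels = small_case.labels_supine
        mesh = voxel_to_hex_mesh(labels, 4.0)
        gland = labels.mask(Label.FIBROGLANDULAR, Label.LESION)
        dil = binary_dilation(gland, iterations=3)
        centers = mesh.nodes[mesh.elements].mean(axis=1)
        idx = np.rint(labels.world_to_index(centers)).astype(int)
        idx = np.clip(idx, 0, np.array(labels.shape) - 1)
        is_gland = mesh.element_tissue == TISSUE_FIBROGLANDULAR
        inside = dil[tuple(idx[is_gland].T)]
        assert inside.mean() > 0.97

    def test_chest_wall_nodes_on_wall_plane(self, hemi_mesh):
        assert len(hemi_mesh.chest_wall_nodes) > 0
        y = hemi_mesh.nodes[hemi_mesh.chest_wall_nodes, hemi_mesh.ap_axis]
        assert np.allclose(y, y.min())

    def test_nipple_node_on_surface(self, hemi_mesh):
        assert hemi_mesh.nipple_node in hemi_mesh.surface_node_set()
        apex = hemi_mesh.nodes[hemi_mesh.nipple_node]
        assert apex[1] > 0.8 * 20.0       # near the anterior pole


class TestAddSkinLayer:
    def test_zero_thickness_is_identity(self, hemi_mesh):
        assert add_skin_layer(hemi_mesh, 0.0) is hemi_mesh

    def test_flat_surface_prism_volumes(self):
        mesh = voxel_to_hex_mesh(cube_labels(n_vox=6, spacing=2.0), 4.0)
        n_facets = len(mesh.surface_facets)
        out = add_skin_layer(mesh, 1.0)
        skin = out.element_tissue == TISSUE_SKIN
        assert skin.sum() == n_facets
        # prisms over interior facets of a flat face (all four offsets
        # along the same axis) have exactly facet-area x thickness volume;
        # closed-corner prisms legitimately differ
        vols = out.element_volumes()[skin]
        elems = out.elements[skin]
        offsets = out.nodes[elems[:, 4:]] - out.nodes[elems[:, :4]]
        flat = (np.abs(offsets - offsets[:, :1]) < 1e-9).all(axis=(1, 2))
        assert flat.sum() > 0
        np.testing.assert_allclose(vols[flat], 16.0, rtol=1e-9)

    def test_hemisphere_skin_volume_close_to_area(self, hemi_mesh):
        out = add_skin_layer(hemi_mesh, 1.0)
        skin_vol = out.element_volumes()[out.element_tissue == TISSUE_SKIN].sum()
        # stair-step voxel surfaces exceed the smooth area; compare against
        # the summed facet area instead of the analytic hemisphere
        f = hemi_mesh.surface_facets
        v1 = hemi_mesh.nodes[f[:, 1]] - hemi_mesh.nodes[f[:, 0]]
        v2 = hemi_mesh.nodes[f[:, 3]] - hemi_mesh.nodes[f[:, 0]]
        area = np.linalg.norm(np.cross(v1, v2), axis=1).sum()
        assert skin_vol == pytest.approx(area * 1.0, rel=0.10)

    def test_jacobians_positive_after_extrusion(self, hemi_mesh):
        out = add_skin_layer(hemi_mesh, 1.0)
        assert out.jacobians_positive()

    def test_skin_conformal_to_surface_nodes(self, hemi_mesh):
        out = add_skin_layer(hemi_mesh, 1.0)
        skin_elems = out.elements[out.element_tissue == TISSUE_SKIN]
        # bottom face nodes of every skin element are original surface nodes
        assert np.isin(skin_elems[:, :4], hemi_mesh.surface_node_set()).all()


class TestMeshConvergence:
    def test_equal_sizes_zero_change(self, hemi_labels, materials,
                                     fast_fem_config):
        rep = mesh_convergence_check(hemi_labels, materials, fast_fem_config,
                                     sizes=[4.0, 4.0],
                                     nipple_mm=np.array([0.0, 20.0, 0.0]))
        assert rep["changes"][0]["rel_change_nipple"] == pytest.approx(0.0,
                                                                       abs=1e-9)
        assert rep["converged_size"] == 4.0

    def test_ascending_sizes_rejected(self, hemi_labels, materials):
        with pytest.raises(ValueError):
            mesh_convergence_check(hemi_labels, materials, None,
                                   sizes=[4.0, 8.0])

    def test_refinement_ladder_reports_changes(self, hemi_labels, materials,
                                               fast_fem_config):
        rep = mesh_convergence_check(hemi_labels, materials, fast_fem_config,
                                     sizes=[8.0, 4.0],
                                     nipple_mm=np.array([0.0, 20.0, 0.0]))
        assert not rep["runs"][0]["failed"] and not rep["runs"][1]["failed"]
        assert rep["runs"][1]["n_elements"] > rep["runs"][0]["n_elements"]
        assert rep["changes"][0]["rel_change_nipple"] >= 0.0


class TestVtkExport:
    def test_written_file_round_trips_counts(self, hemi_mesh, tmp_path):
        path = tmp_path / "mesh.vtk"
        write_vtk(hemi_mesh, path, point_data={"u": np.zeros((hemi_mesh.n_nodes, 3))})
        text = path.read_text()
        assert f"POINTS {hemi_mesh.n_nodes} double" in text
        assert f"CELLS {hemi_mesh.n_elements}" in text
        assert "VECTORS u double" in text
        # node coordinates parse back identically
        lines = text.splitlines()
        i = lines.index(f"POINTS {hemi_mesh.n_nodes} double") + 1
        pts = np.loadtxt(lines[i:i + hemi_mesh.n_nodes])
        np.testing.assert_allclose(pts, hemi_mesh.nodes, rtol=1e-7)
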