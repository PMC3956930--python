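import pytest

from rgccam import Tree, build_cam_matrix, load_genetic_code

YEAST_TAXA = ("c", "p", "m", "k", "b")
YEAST_NEWICK = "((c,p),m,(k,b));"


@pytest.fixture(scope="session")
def standard_code():
    return load_genetic_code("standard")


@pytest.fixture(scope="session")
def cam_matrix(standard_code):
    return build_cam_matrix(standard_code)


@pytest.fixture(scope="session")
def yeast_tree():
    return Tree.from_newick(YEAST_NEWICK)


@pytest.fixture()
def toy_fasta(tmp_path):
    """Five taxa, eight columns: one CAM column (N/C, index 2), one non-CAM
    column (D/H, index 6), the rest constant."""
    path = tmp_path / "toy.fasta"
    rows = {
        "c": "MANGDKLD",
        "p": "MANGDKLD",
        "m": "MANGDKLD",
        "k": "MACGDKHD",
        "b": "MACGDKHD",
    }
    path.write_text("".join(f">{t}\n{s}\n" for t, s in rows.items()))
    return path
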