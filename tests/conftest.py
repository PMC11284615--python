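"""Shared fixtures: synthetic study bundles and databases built per session.

Everything is generated programmatically from seeded specs — no stored data
files. Session-scoped fixtures are read-only; tests that mutate a database
build their own through ``make_db``.
"""

from __future__ import annotations

import pytest

from sendhc import db as dbm
from sendhc import fixtures, query, vocab


@pytest.fixture(scope="session")
def default_root(tmp_path_factory):
    """Three-study root: one TCNTRL-less, one full, one SE-less/TS-only."""
    root = tmp_path_factory.mktemp("root")
    _, truths = fixtures.make_default_root(root, base_seed=7)
    return root, truths


def build_db(path, root):
    handle = dbm.init_environment(path, create=True)
    dbm.create_schema(handle)
    report = dbm.import_studies(handle, root)
    assert report.count("failed") == 0, report.entries
    return handle


@pytest.fixture()
def make_db(tmp_path):
    """Factory for a private, mutable database loaded from a study root."""
    handles = []

    def _make(root):
        handle = build_db(tmp_path / f"db{len(handles)}.sqlite", root)
        handles.append(handle)
        return handle

    yield _make
    for handle in handles:
        dbm.disconnect(handle)


@pytest.fixture(scope="session")
def default_db(default_root, tmp_path_factory):
    """Read-only database over the default three-study root."""
    root, truths = default_root
    handle = build_db(tmp_path_factory.mktemp("db") / "hc.sqlite", root)
    dbm.create_indexes(handle)
    yield handle, truths
    dbm.disconnect(handle)


@pytest.fixture(scope="session")
def ct_vocab(tmp_path_factory):
    """The packaged synthetic CT fixture parsed into a VocabMap."""
    path = fixtures.make_ct_fixture(tmp_path_factory.mktemp("ct") / "ct.tsv")
    return path, vocab.gen_vocab([path])


@pytest.fixture(scope="session")
def usecase2(tmp_path_factory, ct_vocab):
    """The 873-animal harmonization cohort: raw and cleaned databases."""
    base = tmp_path_factory.mktemp("uc2")
    raw = base / "raw"
    _, truth = fixtures.make_usecase2_fixture(raw, seed=11)
    ct_path, vmap = ct_vocab
    clean = base / "clean"
    report = vocab.standardize_file(raw, clean, vmap)
    pre = build_db(base / "pre.sqlite", raw)
    post = build_db(base / "post.sqlite", clean)
    yield {
        "raw": raw, "clean": clean, "truth": truth, "report": report,
        "vocab": vmap, "pre": pre, "post": post,
    }
    dbm.disconnect(pre)
    dbm.disconnect(post)


def control_chain(handle, vmap=None, **kwargs):
    """The full filter chain with null criteria unless overridden."""
    studies = query.get_studies_sdesign(handle, kwargs.get("design"))
    studies = query.get_studies_ststdtc(
        handle, kwargs.get("from_date"), kwargs.get("to_date"), prior=studies
    )
    subjects = query.get_control_subj(
        handle, studies, incl_uncertain=kwargs.get("incl_uncertain", False),
        vocab=vmap,
    )
    subjects = query.get_subj_sex(handle, subjects, kwargs.get("sex"), vocab=vmap)
    subjects = query.get_subj_species_strain(
        handle, subjects, kwargs.get("species"), kwargs.get("strain"), vocab=vmap
    )
    subjects = query.get_subj_route(handle, subjects, kwargs.get("route"),
                                    vocab=vmap)
    return subjects
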