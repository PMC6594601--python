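"""Shared fixtures: tiny hand-built collections and normalization helpers."""

from __future__ import annotations

import pytest

from herblink.io import Collection, Specimen
from herblink.normalize import default_lexicons, normalize_name


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def N(lexicons):
    """Shorthand: raw string -> normalized OriginalName."""
    def _n(raw):
        return normalize_name(raw, lexicons)
    return _n


# The two historically attested four-name sets for Barbarea vulgaris --------

BARBAREA_QUERY = ["Robertina", "Herba Sancti Alberti", "Adarca",
                  "Erisimi species"]
BARBAREA_TARGET = ["Erysimum quibusdam", "Albertina vulgo",
                   "Herba Sancti Alberti", "Robertina"]


@pytest.fixture(scope="session")
def barbarea_names(N):
    return ([N(x) for x in BARBAREA_QUERY], [N(x) for x in BARBAREA_TARGET])


def make_collection(cid, rows, unit_mode="specimen"):
    """rows: iterable of (specimen_no, [names], determination)."""
    return Collection(
        id=cid,
        specimens=[
            Specimen(collection_id=cid, specimen_no=no,
                     original_names=tuple(names), determination=det)
            for no, names, det in rows
        ],
        unit_mode=unit_mode,
    )


@pytest.fixture
def toy_pair():
    """3-unit query vs 4-specimen target engineered to hit 100, 50 and 0."""
    query = make_collection("Q", [
        (1, ["Terebinthus"], "Pistacia terebinthus"),
        (2, ["Robertina", "Adarca", "Sideritis"], "Barbarea vulgaris"),
        (3, ["Lupha"], "Colocasia esculenta"),
    ])
    target = make_collection("T", [
        (1, ["Terebinthus"], "Pistacia terebinthus"),       # exact -> 100
        (2, ["Robertina", "Cardamine"], "Barbarea vulgaris"),  # 1/3 -> 50
        (3, ["Potamogeton"], "Potamogeton natans"),         # decoy
        (4, ["Geranium primum"], "Geranium molle"),         # decoy
    ])
    return query, target
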