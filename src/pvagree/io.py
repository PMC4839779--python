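"""File formats and packaged example data.

Formats
-------
* Observations: CSV with header ``n_treated,price_eur`` (UTF-8, dot decimal).
* Model: flat JSON ``{drug, f_price, decay_k, half_life_const}`` with a
  deterministic field order; round-trip safe.
* Agreement descriptor: JSON ``{drug, f_price_eur, tot_pt, data_pairs}``,
  where ``data_pairs`` is a list of ``[n_treated, price_eur]`` pairs that the
  model is fitted from (exactly two pairs -> exact fit; more -> least squares).
* Nomogram: CSV with header ``nwbi_eur,php_pct`` plus a JSON sidecar
  recording the interpolation mode and a provenance label.

Two worked examples ship with the package: ranibizumab in macular
degeneration ((0, 9050), (20000, 6500) EUR) and sofosbuvir in hepatitis C
((0, 37500), (60000, 4000) EUR), both reconstructed from publicly released
figures about confidential Italian national agreements.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import (
    DegenerateInputError,
    PriceVolumeModel,
    PriceVolumePoint,
    fit_log_linear,
    fit_two_points,
)
from .expenditure import Agreement
from .nomogram import Nomogram, NomogramPoint

__all__ = [
    "FIXTURE_DRUGS",
    "read_points_csv",
    "write_points_csv",
    "model_to_dict",
    "model_from_dict",
    "write_model_json",
    "read_model_json",
    "fit_points",
    "agreement_from_dict",
    "read_agreement_json",
    "write_nomogram_csv",
    "read_nomogram_csv",
    "load_fixture_points",
    "load_fixture_agreement",
    "reference_nomogram",
]

FIXTURE_DRUGS = ("ranibizumab", "sofosbuvir")


# -- observations ------------------------------------------------------------

def read_points_csv(path: str | Path) -> list[PriceVolumePoint]:
    df = pd.read_csv(path)
    missing = {"n_treated", "price_eur"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        PriceVolumePoint(float(r.n_treated), float(r.price_eur))
        for r in df.itertuples(index=False)
    ]


def write_points_csv(points: list[PriceVolumePoint], path: str | Path) -> None:
    pd.DataFrame(
        {"n_treated": [p.n_treated for p in points], "price_eur": [p.price for p in points]}
    ).to_csv(path, index=False)


# -- model JSON --------------------------------------------------------------

def model_to_dict(model: PriceVolumeModel, drug: str = "") -> dict:
    return {
        "drug": drug,
        "f_price": model.f_price,
        "decay_k": model.decay_k,
        "half_life_const": model.half_life_const,
    }


def model_from_dict(d: dict) -> tuple[PriceVolumeModel, str]:
    for key in ("f_price", "decay_k", "half_life_const"):
        if key not in d:
            raise ValueError(f"model JSON missing field {key!r}")
    model = PriceVolumeModel(
        f_price=float(d["f_price"]),
        decay_k=float(d["decay_k"]),
        half_life_const=float(d["half_life_const"]),
    )
    return model, str(d.get("drug", ""))


def write_model_json(model: PriceVolumeModel, path: str | Path, drug: str = "") -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, drug), indent=2) + "\n")


def read_model_json(path: str | Path) -> tuple[PriceVolumeModel, str]:
    return model_from_dict(json.loads(Path(path).read_text()))


# -- agreements --------------------------------------------------------------

def fit_points(points: list[PriceVolumePoint], half_life_const: float) -> PriceVolumeModel:
    """Dispatch: exact fit for exactly two points, least squares for more."""
    if len(points) < 2:
        raise DegenerateInputError("need at least 2 points")
    if len(points) == 2:
        return fit_two_points(points[0], points[1], half_life_const=half_life_const)
    return fit_log_linear(points, half_life_const=half_life_const)


def agreement_from_dict(d: dict, half_life_const: float = 0.693) -> Agreement:
    for key in ("drug", "f_price_eur", "tot_pt", "data_pairs"):
        if key not in d:
            raise ValueError(f"agreement JSON missing field {key!r}")
    points = [PriceVolumePoint(float(n), float(p)) for n, p in d["data_pairs"]]
    model = fit_points(points, half_life_const=half_life_const)
    return Agreement(drug=str(d["drug"]), model=model, tot_pt=float(d["tot_pt"]))


def read_agreement_json(path: str | Path, half_life_const: float = 0.693) -> Agreement:
    return agreement_from_dict(json.loads(Path(path).read_text()), half_life_const)


# -- nomogram files ----------------------------------------------------------

def write_nomogram_csv(
    nomogram: Nomogram, path: str | Path, provenance: str = ""
) -> None:
    """Write reference points as CSV; interpolation mode and provenance go to
    a ``.json`` sidecar next to the CSV."""
    path = Path(path)
    pd.DataFrame(
        {"nwbi_eur": [p.nwbi for p in nomogram.points],
         "php_pct": [p.php_pct for p in nomogram.points]}
    ).to_csv(path, index=False)
    sidecar = {"interpolation": nomogram.interpolation, "provenance": provenance}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_nomogram_csv(path: str | Path) -> tuple[Nomogram, str]:
    path = Path(path)
    df = pd.read_csv(path)
    points = tuple(
        NomogramPoint(float(r.nwbi_eur), float(r.php_pct)) for r in df.itertuples(index=False)
    )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    interpolation, provenance = "log_linear", ""
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        interpolation = sidecar.get("interpolation", "log_linear")
        provenance = sidecar.get("provenance", "")
    return Nomogram(points=points, interpolation=interpolation), provenance


# -- packaged fixtures -------------------------------------------------------

def _data_path(name: str):
    return resources.files("pvagree.data").joinpath(name)


def load_fixture_points(drug: str) -> list[PriceVolumePoint]:
    """Observations for a shipped example (``ranibizumab`` or ``sofosbuvir``)."""
    if drug not in FIXTURE_DRUGS:
        raise ValueError(f"unknown fixture {drug!r}; available: {FIXTURE_DRUGS}")
    with resources.as_file(_data_path(f"{drug}.csv")) as p:
        return read_points_csv(p)


def load_fixture_agreement(drug: str, half_life_const: float = 0.693) -> Agreement:
    """Full agreement (model + candidate population) for a shipped example."""
    if drug not in FIXTURE_DRUGS:
        raise ValueError(f"unknown fixture {drug!r}; available: {FIXTURE_DRUGS}")
    with resources.as_file(_data_path(f"{drug}_agreement.json")) as p:
        return read_agreement_json(p, half_life_const)


def reference_nomogram(half_life_const: float = 0.693) -> Nomogram:
    """The reconstructed two-point reference nomogram.

    Built from the two shipped agreements.  The candidate-population anchors
    (20,000 for ranibizumab; 60,000 for sofosbuvir) are reconstructed from
    public reporting, not taken from the confidential agreements, so treat
    predictions as indicative.
    """
    from .nomogram import build_nomogram

    return build_nomogram(
        [load_fixture_agreement(d, half_life_const) for d in FIXTURE_DRUGS]
    )
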