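import pytest

from uvvisdb.fixtures import FixtureSpec, gen_records
from uvvisdb.records import CompoundRecord, Peak, UvVisEntry


@pytest.fixture
def worked_example_doc():
    """A document in the deposit schema for a known real compound."""
    return {
        "inchikey": "WAJKAWOYYMLWNI-UHFFFAOYSA-N",
        "PRISTINE": {
            "SMI": ["CCOC(=O)C1=CC=CC=C1"],
            "uvvis": [
                {
                    "doi": "10.1000/example.1",
                    "solvent": "ethanol",
                    "peaks": [
                        {
                            "lambda": 416.0,
                            "lambda_unit": "nm",
                            "extinction": 30000.0,
                            "extinction_unit": "L mol-1 cm-1",
                        },
                        {
                            "lambda": 514.0,
                            "lambda_unit": "nm",
                            "extinction": "NULL",
                            "extinction_unit": "NULL",
                        },
                    ],
                }
            ],
        },
    }


@pytest.fixture
def small_records():
    return gen_records(FixtureSpec(n_compounds=10, seed=11))


@pytest.fixture
def record_factory():
    def make(key="AAAAAAAAAAAAAA-BBBBBBBBBB-N", wavelengths=(400.0,), doi="10.1/x",
             solvent=None, extinctions=None):
        peaks = []
        for i, wl in enumerate(wavelengths):
            eps = None
            if extinctions is not None and i < len(extinctions):
                eps = extinctions[i]
            peaks.append(
                Peak(
                    wavelength=wl,
                    wavelength_unit="nm",
                    extinction=eps,
                    extinction_unit="L mol-1 cm-1" if eps is not None else None,
                )
            )
        return CompoundRecord(
            inchikey=key,
            smiles=["c1ccccc1"],
            uvvis=[UvVisEntry(doi=doi, peaks=peaks, solvent=solvent)],
        )

    return make
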