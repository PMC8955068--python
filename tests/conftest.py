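import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("repeatable", derandomize=True, deadline=None)
_hsettings.load_profile("repeatable")

from nanoform import fixtures as fx
from nanoform import rsm
from nanoform.config import default_study_config


@pytest.fixture(scope="session")
def design17():
    return fx.bbd_design_matrix()


@pytest.fixture(scope="session")
def config():
    return default_study_config()


@pytest.fixture(scope="session")
def ps_model(design17):
    return rsm.fit_rsm(design17, fx.response_values("PS"),
                       rsm.TermSet.linear(), rsm.SQRT, "PS")


@pytest.fixture(scope="session")
def ee_model(design17):
    full = rsm.fit_rsm(design17, fx.response_values("EE"),
                       rsm.TermSet.full_quadratic(), rsm.INVERSE, "EE")
    return rsm.reduce_model(full, alpha=0.05)


@pytest.fixture(scope="session")
def cdr_model(design17):
    return rsm.fit_rsm(design17, fx.response_values("CDR"),
                       rsm.TermSet.linear(), rsm.IDENTITY, "CDR")


@pytest.fixture(scope="session")
def fitted_models(ps_model, ee_model, cdr_model):
    return {"PS": ps_model, "EE": ee_model, "CDR": cdr_model}


@pytest.fixture()
def design_csv(tmp_path):
    """The embedded 17-run table written out as a CSV file."""
    import pandas as pd
    path = tmp_path / "design.csv"
    pd.DataFrame(fx.bbd_run_table()).to_csv(path, index=False)
    return path
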