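"""Reference biochemical measurements for five bloom-forming algae.

Mean and coefficient of variation (as a fraction) of triplicate harvest
measurements for one diatom, two haptophytes and two dinoflagellates
grown under replete, low-nitrogen and low-phosphorus conditions:
growth rate (d^-1), POC and PON (pmol/cell), molar C:N, particulate
carbohydrate (pmol glucose equivalents/cell), chlorophyll a (ug/cell)
and Fv/Fm (dimensionless).  These means parameterize the physiology
replicate generator and the worked C:N examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Variables present in the reference table. ``CN`` is the printed molar
#: ratio; replicate generation derives C:N from POC/PON instead, so
#: drop it via ``load_reference_physiology(include_cn=False)``.
REFERENCE_VARIABLES = (
    "growth_rate",
    "POC",
    "PON",
    "CN",
    "pCHO",
    "chl_a",
    "FvFm",
)


def load_reference_physiology(include_cn: bool = True) -> pd.DataFrame:
    """Long-format reference means: species, treatment, variable, mean, cv."""
    path = resources.files("orthostress").joinpath("data/reference_physiology.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    if not include_cn:
        df = df[df["variable"] != "CN"].reset_index(drop=True)
    return df
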