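"""Bundled example data.

The English League football table: 20 clubs, with the number of won
matches as the count response and five club statistics as regressors.
The published table stores the two goal columns as goals conceded (X3)
and goal difference (X4); the regression design analysed alongside it
uses goals scored and goals conceded, recovered as ``scored = X3 + X4``
and ``conceded = X3``.  The derived design reproduces the published
post-deletion coefficient changes exactly, which pins the convention.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .glm import ModelData

__all__ = ["load_english_league", "read_csv_data"]

DESIGN_NAMES = ["yellow_cards", "red_cards", "goals_scored", "goals_conceded", "points"]


def load_english_league(as_printed: bool = False):
    """Load the football data.

    Parameters
    ----------
    as_printed : bool
        If True, return the published 20 x 6 table as a DataFrame
        (columns Y, X1..X5, with X3 = goals conceded and X4 = goal
        difference).  If False (default), return a :class:`ModelData`
        with the five-regressor analysis design (goals scored / conceded
        derived from the printed columns).
    """
    with resources.files("poisliu.data").joinpath("english_league.csv").open() as fh:
        table = pd.read_csv(fh)
    if as_printed:
        return table
    X = np.column_stack(
        [
            table["X1"],
            table["X2"],
            table["X3"] + table["X4"],  # goals scored
            table["X3"],  # goals conceded
            table["X5"],
        ]
    ).astype(float)
    return ModelData(y=table["Y"].to_numpy(), X=X, names=list(DESIGN_NAMES))


def read_csv_data(
    path, response: str, delimiter: str = ",", add_intercept: bool = True
) -> ModelData:
    """Read a delimited text file into a :class:`ModelData`.

    The header row names the columns; ``response`` selects the count
    column and every remaining numeric column becomes a regressor.
    """
    frame = pd.read_csv(path, sep=delimiter)
    if response not in frame.columns:
        raise ValueError(f"response column {response!r} not found in {list(frame.columns)}")
    y = frame[response].to_numpy()
    rest = frame.drop(columns=[response])
    return ModelData(
        y=y,
        X=rest.to_numpy(dtype=float),
        add_intercept=add_intercept,
        names=list(rest.columns),
    )
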