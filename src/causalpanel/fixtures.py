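"""Packaged reference tables: advocacy-account list and the reference link table.

Two small CSV resources ship with the package:

* ``accounts.csv`` — the 20 anti-/proregulation advocacy Twitter accounts
  (handle, organization, follower count, post count) whose daily post
  counts form two of the six study variables.
* ``links.csv`` — the 13 labelled causal links (a–m) of the six-variable
  reference network: source, sink, delay in days, p-value as printed,
  signed partial correlation, and link persistence.  Censored p-values
  are stored as the printed bound (``<0.001``) and parsed to that bound.

The link table doubles as the ground truth for the study-mimic simulator.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .graphs import CausalLink

__all__ = [
    "VARIABLES",
    "AccountRecord",
    "load_account_fixture",
    "load_account_table",
    "load_link_fixture",
    "load_link_table",
]

#: Canonical variable order for the six-variable study network.
VARIABLES = (
    "media_laws",        # media coverage of firearm laws and regulation
    "media_shootings",   # media coverage of mass shootings
    "media_crime",       # media coverage of violent crime
    "tweets_anti",       # posts by antiregulation organizations
    "tweets_pro",        # posts by proregulation organizations
    "background_checks",  # NICS background checks (firearm-acquisition proxy)
)


@dataclass(frozen=True)
class AccountRecord:
    category: str
    handle: str
    organization: str
    followers: int
    posts: int


def _resource(name: str):
    return resources.files("causalpanel").joinpath("data", name)


def load_account_table() -> pd.DataFrame:
    """The account list verbatim, as a DataFrame."""
    with resources.as_file(_resource("accounts.csv")) as path:
        return pd.read_csv(path)


def load_account_fixture() -> list[AccountRecord]:
    table = load_account_table()
    records = [AccountRecord(**row) for row in table.to_dict("records")]
    handles = [r.handle for r in records]
    if len(set(handles)) != len(handles):
        raise ValueError("account handles must be unique")
    return records


def load_link_table() -> pd.DataFrame:
    """The link table verbatim (p-values as printed strings)."""
    with resources.as_file(_resource("links.csv")) as path:
        return pd.read_csv(path, dtype={"p_value": str})


def load_link_fixture() -> list[CausalLink]:
    """The 13 reference links as :class:`CausalLink` objects.

    Variable names are mapped to indices in :data:`VARIABLES` order; a
    censored p-value ``<x`` is parsed to its bound ``x``.
    """
    index = {name: i for i, name in enumerate(VARIABLES)}
    links = []
    for row in load_link_table().to_dict("records"):
        links.append(
            CausalLink(
                source=index[row["source"]],
                sink=index[row["sink"]],
                lag=int(row["lag"]),
                p_value=float(str(row["p_value"]).lstrip("<")),
                rho=float(row["rho"]),
                orientation="directed",
                label=row["label"],
            )
        )
    return links
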