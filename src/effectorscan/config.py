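"""Run configuration and logging setup.

A :class:`RunConfig` carries every fixed constant of the screen: the cumulative
expression fraction behind the N99 threshold (0.99), the minimum number of
distinct proteomic peptides required to call a venom protein (3), and the
significance level of the high-expression Z test (0.05).
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

logger = logging.getLogger("effectorscan")

#: Keyword lists used to assign coarse functional classes from free-text
#: annotation.  Matching is case-insensitive substring; class priority is
#: digestion > ribosome > immunity.
DEFAULT_DIGESTION_KEYWORDS: tuple[str, ...] = (
    "trypsin",
    "chymotrypsin",
    "protease",
    "proteinase",
    "peptidase",
    "lipase",
    "amylase",
    "glucosidase",
    "carboxypeptidase",
    "esterase",
)
DEFAULT_RIBOSOME_KEYWORDS: tuple[str, ...] = ("ribosom",)
DEFAULT_IMMUNITY_KEYWORDS: tuple[str, ...] = (
    "immun",
    "lectin",
    "defensin",
    "serpin",
    "antimicrobial",
    "lysozyme",
)

EXPRESSED_RULES = ("inclusive_ge", "strict_gt")


def setup_logging(verbose: bool = False) -> None:
    """Log to standard error; results never go to the log stream."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Parameters
    ----------
    seed:
        Master seed; reproduces identical outputs end to end.
    n99_fraction:
        Fraction of summarized transcript abundance that defines the
        expressed-gene threshold (default 0.99, i.e. N99).
    min_peptides:
        Minimum number of distinct, fully aligned proteomic peptides for a
        venom-protein call (default 3).
    alpha:
        Significance level of the one-sided high-expression Z test
        (default 0.05).
    expressed_rule:
        Whether a gene sitting exactly at the threshold counts as expressed
        (``inclusive_ge``, default) or not (``strict_gt``).
    il_equivalence:
        Treat isoleucine and leucine as interchangeable during peptide
        matching (off by default).
    """

    seed: int = 0
    n99_fraction: float = 0.99
    min_peptides: int = 3
    alpha: float = 0.05
    expressed_rule: str = "inclusive_ge"
    il_equivalence: bool = False
    digestion_keywords: tuple[str, ...] = DEFAULT_DIGESTION_KEYWORDS
    ribosome_keywords: tuple[str, ...] = DEFAULT_RIBOSOME_KEYWORDS
    immunity_keywords: tuple[str, ...] = DEFAULT_IMMUNITY_KEYWORDS
    outlier_cutoff: float = 5.0
    venom_tissue: str = "venom_gland"
    teratocyte_tissue: str = "teratocyte"
    focal_species: str = "focal_sp"
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.n99_fraction < 1:
            raise ConfigError(
                f"n99_fraction must lie in (0, 1); got {self.n99_fraction}"
            )
        if self.min_peptides < 1:
            raise ConfigError(f"min_peptides must be >= 1; got {self.min_peptides}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1); got {self.alpha}")
        if self.expressed_rule not in EXPRESSED_RULES:
            raise ConfigError(
                f"expressed_rule must be one of {EXPRESSED_RULES}; "
                f"got {self.expressed_rule!r}"
            )
        if int(self.seed) != self.seed:
            raise ConfigError(f"seed must be an integer; got {self.seed!r}")
        self.digestion_keywords = tuple(
            str(k).lower() for k in self.digestion_keywords
        )
        self.ribosome_keywords = tuple(str(k).lower() for k in self.ribosome_keywords)
        self.immunity_keywords = tuple(str(k).lower() for k in self.immunity_keywords)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("digestion_keywords", "ribosome_keywords", "immunity_keywords"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a YAML (or JSON; YAML is a superset) config file.

        Keyword arguments override file values; ``None`` overrides are ignored
        so CLI flags that were not passed leave the file value in place.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)
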