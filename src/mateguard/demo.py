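"""Bundled paper-style demo configuration.

One SMD-style two-group comparison, a four-arm exposure-time experiment
routed through Kruskal-Wallis and Dunn's test, fecundity and paternity
blocks, and the four-scenario guarding-model sweep.
"""

from __future__ import annotations

import math

from .pipeline import RunConfig
from .simulate import exposure_time_reduction


def demo_config(seed: int = 0) -> RunConfig:
    # exposure arms at or below 6 h show no shortening, arms at or above
    # 12 h show the full effect; encoded via the condition label per arm
    exposure_groups = [
        ["CS_2h", "naive" if exposure_time_reduction(2.0) == 0 else "experienced", 36],
        ["CS_6h", "naive" if exposure_time_reduction(6.0) == 0 else "experienced", 36],
        ["CS_12h", "experienced", 36],
        ["CS_24h", "experienced", 36],
    ]
    experiments = [
        {
            "name": "smd_cs",
            "kind": "md",
            "design": {"percent_reduction": 15.7},
            "plan": {"reference": "naive"},
        },
        {
            "name": "exposure_time",
            "kind": "md",
            "design": {
                "groups": [["CS_naive", "naive", 36]] + exposure_groups,
                "percent_reduction": exposure_time_reduction(24.0),
            },
            "plan": {
                "group_by": ["genotype"],
                "reference": "CS_naive",
            },
        },
        {"name": "fecundity", "kind": "fecundity", "design": {}},
        {"name": "paternity", "kind": "paternity", "design": {}},
        {"name": "calexa", "kind": "calexa", "design": {}},
    ]
    model = {
        "naive": {"alpha": 1.0, "beta": 1.0, "gamma": 1.5},
        "experienced": {"alpha": 1.3, "beta": 1.0, "gamma": 1.5},
        "solver": {"method": "closed_form"},
        "sweeps": [
            {"name": "gamma", "which": "gamma", "from": 0.05, "to": 2.0 * math.e, "steps": 120},
            {"name": "alpha", "which": "alpha", "from": 0.5, "to": 2.0, "steps": 60},
        ],
    }
    return RunConfig.from_dict({"seed": seed, "experiments": experiments, "model": model})
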