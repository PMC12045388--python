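"""Declarative scenario files (YAML) for the synthetic-cohort generator."""

from __future__ import annotations

import yaml

from .cohort import Covariate, LinearModel, SimulationScenario, default_scenario

__all__ = ["scenario_to_yaml", "scenario_from_yaml"]


def _linear_to_dict(m: LinearModel) -> dict:
    return {"intercept": float(m.intercept), "coefs": {k: v for k, v in m.coefs.items()}}


def scenario_to_yaml(scenario: SimulationScenario, path) -> None:
    doc = {
        "n_records": scenario.n_records,
        "seed": scenario.seed,
        "program_mix": list(map(float, scenario.program_mix)),
        "rfc_mix": list(map(float, scenario.rfc_mix)),
        "true_treatment_logor": float(scenario.true_treatment_logor),
        "misspec": scenario.misspec,
        "misspec_confounder": scenario.misspec_confounder,
        "rfc_structural_missingness": scenario.rfc_structural_missingness,
        "covariates": [
            {
                "name": c.name,
                "kind": c.kind,
                "probs": list(map(float, c.probs)) if c.levels else float(c.probs),
                **({"levels": list(c.levels)} if c.levels else {}),
                **({"rfc_domain": c.rfc_domain} if c.rfc_domain else {}),
            }
            for c in scenario.covariate_spec
        ],
        "propensity": _linear_to_dict(scenario.propensity),
        "outcome": _linear_to_dict(scenario.outcome),
        "subgroup_shifts": {
            f"{p}|{r}": [float(a), float(b)] for (p, r), (a, b) in scenario.subgroup_shifts.items()
        },
        "missingness": {k: float(v) for k, v in scenario.missingness.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> SimulationScenario:
    """Load a scenario; ``default: true`` builds the study-condition default
    (optionally overriding n_records / seed / true_treatment_logor)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("scenario file must contain a mapping")
    if doc.get("default"):
        kwargs = {
            k: doc[k]
            for k in ("n_records", "seed", "true_treatment_logor", "misspec", "misspec_confounder")
            if k in doc
        }
        return default_scenario(**kwargs)
    covariates = tuple(
        Covariate(
            name=c["name"],
            kind=c["kind"],
            probs=tuple(c["probs"]) if isinstance(c["probs"], list) else c["probs"],
            levels=tuple(c["levels"]) if "levels" in c else None,
            rfc_domain=c.get("rfc_domain"),
        )
        for c in doc["covariates"]
    )
    shifts = {}
    for key, val in (doc.get("subgroup_shifts") or {}).items():
        program, rfc = key.split("|", 1)
        shifts[(program, rfc)] = (float(val[0]), float(val[1]))
    return SimulationScenario(
        n_records=int(doc["n_records"]),
        seed=int(doc["seed"]),
        program_mix=tuple(doc["program_mix"]),
        rfc_mix=tuple(doc["rfc_mix"]),
        covariate_spec=covariates,
        propensity=LinearModel(float(doc["propensity"]["intercept"]), doc["propensity"].get("coefs", {})),
        outcome=LinearModel(float(doc["outcome"]["intercept"]), doc["outcome"].get("coefs", {})),
        true_treatment_logor=float(doc["true_treatment_logor"]),
        subgroup_shifts=shifts,
        missingness=doc.get("missingness") or {},
        misspec=doc.get("misspec", "none"),
        misspec_confounder=doc.get("misspec_confounder"),
        rfc_structural_missingness=bool(doc.get("rfc_structural_missingness", True)),
    )
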