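"""Flat key-value configuration files.

A config file is plain text, one `key = value` per line, `#` comments.
Pipeline scalars use bare keys (iterations, alpha1..alpha3, kappa,
coincidence_cutoff, mode, threshold); HMM tables use `hmm.` keys and the
energy model `energy.` keys.  Any key omitted keeps its shipped default.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .coupling import MatchScoreParams
from .engine import TurboConfig
from .pair_hmm import HmmParameters, default_hmm_parameters
from .partition import EnergyModel

_STATES = ("aln", "ins1", "ins2")
_BASES = "ACGU"

_ENERGY_SCALARS = (
    "stack_scale", "hairpin_base", "hairpin_decay", "internal_base",
    "internal_decay", "bulge_base", "bulge_decay", "mb_closing", "mb_branch",
    "mb_unpaired", "min_hairpin", "max_internal",
)


def parse_config_text(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in out:
            raise ValueError(f"config line {lineno}: duplicate key {key!r}")
        out[key] = value
    return out


def _hmm_from_keys(kv: dict[str, str], base: HmmParameters) -> HmmParameters:
    t = base.transition.copy()
    ep = base.emission_pair.copy()
    es = base.emission_single.copy()
    touched = False
    for a, sa in enumerate(_STATES):
        for b, sb in enumerate(_STATES):
            key = f"hmm.t_{sa}_{sb}"
            if key in kv:
                t[a, b] = float(kv.pop(key))
                touched = True
    for a, ba in enumerate(_BASES):
        for b, bb in enumerate(_BASES):
            key = f"hmm.e_{ba}{bb}"
            if key in kv:
                ep[a, b] = float(kv.pop(key))
                touched = True
        key = f"hmm.s_{ba}"
        if key in kv:
            es[a] = float(kv.pop(key))
            touched = True
    return HmmParameters(t, ep, es) if touched else base


def _energy_from_keys(kv: dict[str, str], base: EnergyModel) -> EnergyModel:
    changes: dict = {}
    weights = dict(base.pair_weights)
    wtouched = False
    for pt in list(weights):
        key = f"energy.pair_{pt}"
        if key in kv:
            weights[pt] = float(kv.pop(key))
            wtouched = True
    if wtouched:
        changes["pair_weights"] = weights
    for name in _ENERGY_SCALARS:
        key = f"energy.{name}"
        if key in kv:
            raw = kv.pop(key)
            changes[name] = int(raw) if name in ("min_hairpin", "max_internal") \
                else float(raw)
    return replace(base, **changes) if changes else base


def config_from_text(text: str, base: TurboConfig | None = None) -> TurboConfig:
    base = base if base is not None else TurboConfig()
    kv = parse_config_text(text)
    hmm = _hmm_from_keys(kv, base.hmm_params)
    energy = _energy_from_keys(kv, base.energy_model)
    mp = base.match_params
    mp = MatchScoreParams(
        float(kv.pop("alpha1", mp.alpha1)),
        float(kv.pop("alpha2", mp.alpha2)),
        float(kv.pop("alpha3", mp.alpha3)),
    )
    cfg = TurboConfig(
        iterations=int(kv.pop("iterations", base.iterations)),
        match_params=mp,
        kappa=float(kv.pop("kappa", base.kappa)),
        coincidence_cutoff=float(kv.pop("coincidence_cutoff",
                                        base.coincidence_cutoff)),
        mode=kv.pop("mode", base.mode),
        threshold=float(kv.pop("threshold", base.threshold)),
        energy_model=energy,
        hmm_params=hmm,
    )
    if kv:
        raise ValueError(f"unknown config keys: {sorted(kv)}")
    return cfg


def load_config(path: str | Path, base: TurboConfig | None = None) -> TurboConfig:
    return config_from_text(Path(path).read_text(), base)


def config_to_text(cfg: TurboConfig) -> str:
    """Serialize a full configuration, HMM and energy tables included."""
    lines = [
        f"iterations = {cfg.iterations}",
        f"alpha1 = {cfg.match_params.alpha1:.10g}",
        f"alpha2 = {cfg.match_params.alpha2:.10g}",
        f"alpha3 = {cfg.match_params.alpha3:.10g}",
        f"kappa = {cfg.kappa:.10g}",
        f"coincidence_cutoff = {cfg.coincidence_cutoff:.10g}",
        f"mode = {cfg.mode}",
        f"threshold = {cfg.threshold:.10g}",
    ]
    hp = cfg.hmm_params
    for a, sa in enumerate(_STATES):
        for b, sb in enumerate(_STATES):
            lines.append(f"hmm.t_{sa}_{sb} = {hp.transition[a, b]:.12g}")
    for a, ba in enumerate(_BASES):
        for b, bb in enumerate(_BASES):
            lines.append(f"hmm.e_{ba}{bb} = {hp.emission_pair[a, b]:.12g}")
    for a, ba in enumerate(_BASES):
        lines.append(f"hmm.s_{ba} = {hp.emission_single[a]:.12g}")
    em = cfg.energy_model
    for pt, w in sorted(em.pair_weights.items()):
        lines.append(f"energy.pair_{pt} = {w:.10g}")
    for name in _ENERGY_SCALARS:
        lines.append(f"energy.{name} = {getattr(em, name):.10g}")
    return "\n".join(lines) + "\n"
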