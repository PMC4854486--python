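"""Preset stimulation protocols for the model's in-silico experiments.

Each preset encodes one published-style protocol as an event schedule:
glucose steps, agonist additions, conductance/activity changes and receptor
abundance scans.  Concentrations are in μM (glucose 3 mM = 3000 μM),
conductances in pS, times in s.  All presets equilibrate at their initial
inputs before t = 0.
"""

from __future__ import annotations

from .engine import Event, ScenarioConfig

__all__ = ["preset_scenario", "list_scenarios", "GLUCOSE_LOW", "GLUCOSE_HIGH"]

GLUCOSE_LOW = 3000.0    # μM
GLUCOSE_HIGH = 8000.0   # μM
GLP1_STIM = 6.2e-4      # μM
GIP_STIM = 3.42e-3      # μM
AR3_STIM = 3.0          # μM catecholamine
AM3_STIM = 2.2          # μM acetylcholine
AR7_STIM = 82.0         # μM FFAR1/GPR40 agonist


def _cfg(name, **kw) -> ScenarioConfig:
    return ScenarioConfig(name=name, **kw)


def _presets() -> dict[str, ScenarioConfig]:
    return {
        # glucose step then GLP-1 at high glucose
        "fig3": _cfg(
            "fig3",
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH),
                    Event(4000.0, "GLP1", GLP1_STIM)],
            duration=9000.0, sample_dt=5.0),
        # T2D lesion (reduced saturating ATP/ADP) rescued by K_ATP block
        "fig4": _cfg(
            "fig4",
            overrides={"ATD_m": 15.0},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH),
                    Event(3000.0, "g_mKATP", 9000.0)],
            duration=6000.0, sample_dt=5.0),
        # GLP-1 at low glucose, then glucose step, then GIP
        "fig5": _cfg(
            "fig5",
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "GLP1", GLP1_STIM),
                    Event(3000.0, "Glu", GLUCOSE_HIGH),
                    Event(5000.0, "GIP", GIP_STIM)],
            duration=8000.0, sample_dt=5.0),
        # GLP-1 rescue under the T2D lesion
        "fig6": _cfg(
            "fig6",
            overrides={"ATD_m": 15.0},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH),
                    Event(3000.0, "GLP1", GLP1_STIM)],
            duration=6000.0, sample_dt=5.0),
        # catecholamine occlusion of the GLP-1 cAMP response
        "fig7": _cfg(
            "fig7",
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH),
                    Event(3000.0, "AR3", AR3_STIM),
                    Event(5000.0, "GLP1", GLP1_STIM)],
            duration=9000.0, sample_dt=5.0),
        # glucose step then acetylcholine
        "fig8": _cfg(
            "fig8",
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(3000.0, "Glu", GLUCOSE_HIGH),
                    Event(5000.0, "AM3", AM3_STIM)],
            duration=8000.0, sample_dt=5.0),
        # FFAR1 agonist first, then glucose, then acetylcholine
        "fig8_ffar1": _cfg(
            "fig8_ffar1",
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "AR7", AR7_STIM),
                    Event(3000.0, "Glu", GLUCOSE_HIGH),
                    Event(5000.0, "AM3", AM3_STIM)],
            duration=8000.0, sample_dt=5.0),
        # acetylcholine with NALCN channels enabled, low glucose
        "fig9": _cfg(
            "fig9",
            overrides={"g_mNM3": 35000.0},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "AM3", AM3_STIM)],
            duration=5000.0, sample_dt=5.0),
        # GLP-1 then FFAR1 agonist at high glucose
        "fig10": _cfg(
            "fig10",
            inputs={"Glu": GLUCOSE_HIGH},
            events=[Event(1000.0, "GLP1", GLP1_STIM),
                    Event(4000.0, "AR7", AR7_STIM)],
            duration=8000.0, sample_dt=5.0),
        # FFAR1 agonist then GLP-1 at high glucose
        "fig11": _cfg(
            "fig11",
            inputs={"Glu": GLUCOSE_HIGH},
            events=[Event(1000.0, "AR7", AR7_STIM),
                    Event(3000.0, "GLP1", GLP1_STIM)],
            duration=7000.0, sample_dt=5.0),
        # rat-like PDE composition: NALCN on, CaM-PDE reduced, low glucose;
        # acetylcholine then GLP-1
        "fig12": _cfg(
            "fig12",
            overrides={"g_mNM3": 35000.0, "V_cpde": 0.3},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "AM3", AM3_STIM),
                    Event(5000.0, "GLP1", GLP1_STIM)],
            duration=10000.0, sample_dt=5.0),
        # receptor-abundance experiments
        "glp1r_halved": _cfg(
            "glp1r_halved",
            overrides={"Re_GLt": 1.0},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH),
                    Event(4000.0, "GLP1", GLP1_STIM)],
            duration=9000.0, sample_dt=5.0),
        "a2a_tenfold_down": _cfg(
            "a2a_tenfold_down",
            overrides={"Re_ARt": 0.3},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH)],
            duration=6000.0, sample_dt=5.0),
        "a2a_overexpressed": _cfg(
            "a2a_overexpressed",
            overrides={"Re_ARt": 30.0},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH)],
            duration=6000.0, sample_dt=5.0),
        "mr_tenfold_down": _cfg(
            "mr_tenfold_down",
            overrides={"Re_M3t": 0.2},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH)],
            duration=6000.0, sample_dt=5.0),
        "t2d_rescue": _cfg(
            "t2d_rescue",
            overrides={"ATD_m": 15.0},
            inputs={"Glu": GLUCOSE_LOW},
            events=[Event(1000.0, "Glu", GLUCOSE_HIGH),
                    Event(3000.0, "g_mKATP", 9000.0)],
            duration=6000.0, sample_dt=5.0),
    }


def list_scenarios() -> list[str]:
    return sorted(_presets())


def preset_scenario(name: str) -> ScenarioConfig:
    """Return the event schedule and overrides of a named protocol."""
    presets = _presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(presets))}"
        ) from None
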