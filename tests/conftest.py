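import pytest

from carelex import VentEventRow


def vc_row(subject="s01", patient="p01", step=0, *, spo2=95.0, ph=7.38,
           map=75.0, pplat=22.0, fio2=0.5, peep=8.0, rate=16.0,
           tv=450.0, flow=60.0, pause=0.5, bolus=0, event="adjust"):
    """A schema-valid volume-controlled adjust row with overridable fields."""
    return VentEventRow(subject_id=subject, patient_id=patient, step_index=step,
                        event_type=event, spo2=spo2, ph=ph, map=map, pplat=pplat,
                        mode="VC", fio2=fio2, peep=peep, rate=rate,
                        tv=tv, flow=flow, pause=pause, bolus=bolus)


def pc_row(subject="s01", patient="p01", step=0, *, spo2=95.0, ph=7.38,
           map=75.0, pplat=22.0, fio2=0.5, peep=8.0, rate=16.0,
           pinsp=20.0, itime=1.0, bolus=0):
    return VentEventRow(subject_id=subject, patient_id=patient, step_index=step,
                        event_type="adjust", spo2=spo2, ph=ph, map=map, pplat=pplat,
                        mode="PC", fio2=fio2, peep=peep, rate=rate,
                        pinsp=pinsp, itime=itime, bolus=bolus)


@pytest.fixture
def small_vent_rows():
    """One VC patient: baseline, two adjustments, completion."""
    return [
        vc_row(step=0),
        vc_row(step=1, fio2=0.6, rate=14.0, spo2=88.0),
        vc_row(step=2, fio2=0.6, rate=14.0, peep=10.0),
        VentEventRow(subject_id="s01", patient_id="p01", step_index=3,
                     event_type="complete"),
    ]
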