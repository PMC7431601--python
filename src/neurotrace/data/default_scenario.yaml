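# Shipped flight scenario: eight ATC instructions, a fuel-pump caution,
# a silent fuel leak, a TCAS traffic advisory, four spurious electrical
# cautions, a fuel-imbalance caution (excluded from analysis) and an
# engine-fire warning at 16:40. ATC onsets are evenly scheduled between the
# scripted alerts (artifact plumbing, not part of the scripted timeline);
# the eighth ATC slot is reconstructed.
events:
  - {event_id: atc1, kind: ATC, onset_s: 60.0,
     required_changes: [[altitude_select, 280], [speed_select, 220]]}
  - {event_id: atc2, kind: ATC, onset_s: 150.0,
     required_changes: [[altitude_select, 300]]}
  - {event_id: fuel_pump, kind: caution, onset_s: 240.0,
     required_changes: [[right_main_pump, 0]]}
  - {event_id: elec1, kind: spurious, onset_s: 300.0, analysis_included: false}
  - {event_id: atc3, kind: ATC, onset_s: 330.0,
     required_changes: [[altitude_select, 280]]}
  - {event_id: fuel_leak, kind: silent, onset_s: 360.0,
     analysis_included: false, has_marker: false}
  - {event_id: tcas_ta, kind: caution, onset_s: 420.0, analysis_included: false}
  - {event_id: atc4, kind: ATC, onset_s: 450.0,
     required_changes: [[altitude_select, 300]]}
  - {event_id: elec2, kind: spurious, onset_s: 510.0, analysis_included: false}
  - {event_id: atc5, kind: ATC, onset_s: 560.0,
     required_changes: [[altitude_select, 320]]}
  - {event_id: atc6, kind: ATC, onset_s: 640.0,
     required_changes: [[heading_select, 325]]}
  - {event_id: elec3, kind: spurious, onset_s: 700.0, analysis_included: false}
  - {event_id: fuel_imbalance, kind: caution, onset_s: 760.0,
     required_changes: [[fuel_x_feed, 1]], analysis_included: false}
  - {event_id: atc7, kind: ATC, onset_s: 820.0,
     required_changes: [[heading_select, 350]]}
  - {event_id: elec4, kind: spurious, onset_s: 880.0, analysis_included: false}
  - {event_id: atc8, kind: ATC, onset_s: 930.0,
     required_changes: [[speed_select, 240]], reconstructed: true}
  - {event_id: engine_fire, kind: warning, onset_s: 1000.0,
     required_changes: [[fire_extinguish, 1]]}
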