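# Golden cost-weight presets realizing the behavior taxonomy.
# Weight fields per agent:
#   w_err_self / w_vel_self      own error / velocity
#   w_err_partner / w_vel_partner  partner error / velocity (negative => competition)
#   w_force_partner              partner muscle-force state (partner-energy proxy)
#   r_effort                     own control effort (metabolic cost)
# Values were calibrated once against the reference effort/time ratios of the
# golden scenarios and are frozen; see docs/methods.md.
behaviors:
  co_activity:
    roles: [peer, peer]
    symmetric: true
    weights:
      peer: {w_err_self: 12.0, w_vel_self: 0.12, w_err_partner: 0.0,
             w_vel_partner: 0.0, w_force_partner: 0.0, r_effort: 5.0}
  competition:
    roles: [peer, peer]
    symmetric: true
    weights:
      peer: {w_err_self: 2.5, w_vel_self: 0.025, w_err_partner: -2.5,
             w_vel_partner: -0.025, w_force_partner: 0.0, r_effort: 1.0}
  collaboration:
    roles: [peer, peer]
    symmetric: true
    weights:
      peer: {w_err_self: 2.5, w_vel_self: 0.025, w_err_partner: 2.5,
             w_vel_partner: 0.025, w_force_partner: 0.0, r_effort: 1.0}
  assistance:
    roles: [slave, master]
    symmetric: false
    weights:
      slave: {w_err_self: 0.0, w_vel_self: 0.0, w_err_partner: 6.0,
              w_vel_partner: 0.06, w_force_partner: 0.5, r_effort: 1.0}
      master: {w_err_self: 10.0, w_vel_self: 0.1, w_err_partner: 0.0,
               w_vel_partner: 0.0, w_force_partner: 0.0, r_effort: 5.0}
  education:
    roles: [teacher, student]
    symmetric: false
    weights:
      teacher: {w_err_self: 0.0, w_vel_self: 0.0, w_err_partner: 12.0,
                w_vel_partner: 0.12, w_force_partner: 0.0, r_effort: 2.0}
      student: {w_err_self: 16.0, w_vel_self: 0.16, w_err_partner: 0.0,
                w_vel_partner: 0.0, w_force_partner: 0.0, r_effort: 2.0}
      lazy_student: {w_err_self: 6.5, w_vel_self: 0.065, w_err_partner: 0.0,
                     w_vel_partner: 0.0, w_force_partner: 0.0, r_effort: 5.0}
  mutual_assistance:
    roles: [peer, peer]
    symmetric: true
    weights:
      peer: {w_err_self: 2.5, w_vel_self: 0.025, w_err_partner: 2.5,
             w_vel_partner: 0.025, w_force_partner: 0.5, r_effort: 1.0}

# Golden scenario definitions used by the reference table and acceptance runs.
scenarios:
  assistance: {behavior: assistance, roles: [slave, master]}
  collaboration: {behavior: collaboration, roles: [peer, peer]}
  education-hardworking: {behavior: education, roles: [teacher, student]}
  education-lazy: {behavior: education, roles: [teacher, lazy_student]}
  coactivity-antagonistic:
    behavior: co_activity
    roles: [peer, peer]
    # agent 1 is made stronger purely through a lower metabolic weight
    overrides: {agent1: {r_effort: 1.5}}
    target_offset: 0.5
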