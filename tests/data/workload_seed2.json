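{
 "encryption_keys": {
  "OSLT-001": "8d952f9e44a7375595ee933feea964d5fe774dd4d08eeda80bcaa901b2f26ffe"
 },
 "events": [
  {
   "adversarial": false,
   "args": {},
   "expect": "ACCEPT",
   "function": "deploy_regulator",
   "note": "",
   "sender": "regulator-1",
   "target_ref": "DEPLOY",
   "tick": 0,
   "time": 1600000000
  },
  {
   "adversarial": false,
   "args": {
    "authorised_cro": "cro-1",
    "encryption_pubkey": "2e6379b5144597580dd64720f7003a8370c5c0717c3517aa3352e17b4cc9b0a8",
    "sponsor": "Synthetica Pharma Ltd",
    "trial_id": "OSLT-001",
    "window_end": 1600259200,
    "window_start": 1600086400
   },
   "expect": "ACCEPT",
   "function": "register_cta",
   "note": "",
   "sender": "regulator-1",
   "target_ref": "regulator",
   "tick": 1,
   "time": 1600086400
  },
  {
   "adversarial": false,
   "args": {
    "protocol_document_hash": "7e2967d1ed27b45850387dd1150d207cd7354ef163337e365a38ef757df6e1c8",
    "trial_id": "OSLT-001"
   },
   "expect": "ACCEPT",
   "function": "create_trial",
   "note": "",
   "sender": "cro-1",
   "target_ref": "regulator",
   "tick": 2,
   "time": 1600172800
  },
  {
   "adversarial": false,
   "args": {
    "document_hash": "7e2967d1ed27b45850387dd1150d207cd7354ef163337e365a38ef757df6e1c8",
    "endpoints": [
     {
      "definition": "hours from first dose to alleviation of all influenza symptoms",
      "name": "time_to_alleviation_of_symptoms",
      "type": "primary"
     },
     {
      "definition": "occurrence of bronchitis, sinusitis, otitis media or pneumonia",
      "name": "incidence_of_secondary_complications",
      "type": "secondary"
     }
    ],
    "recruitment_end": 1600691200,
    "recruitment_start": 1600345600,
    "trial_end": 1600950400
   },
   "expect": "ACCEPT",
   "function": "deposit_protocol",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 3,
   "time": 1600259200
  },
  {
   "adversarial": false,
   "args": {
    "consent_hash": "03ab219ce174b23d47d278e9539f4598f8cc069b2265b7489f4187b7e7531b4f",
    "demographics": {
     "age_band": "18-",
     "arm": "treatment",
     "sex": "F"
    },
    "subject_id": "OSLT-001-S001"
   },
   "expect": "ACCEPT",
   "function": "add_subject",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 4,
   "time": 1600345600
  },
  {
   "adversarial": false,
   "args": {
    "consent_hash": "2f3b086a6bdc88f65404c9eb6006ec699169c76cf7be75460ac479edfa2ab337",
    "demographics": {
     "age_band": "38-",
     "arm": "placebo",
     "sex": "F"
    },
    "subject_id": "OSLT-001-S002"
   },
   "expect": "ACCEPT",
   "function": "add_subject",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 5,
   "time": 1600432000
  },
  {
   "adversarial": false,
   "args": {
    "encrypted": false,
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S001\", \"value_hours\": 95.4, \"visit\": 1}",
    "subject_id": "OSLT-001-S001"
   },
   "expect": "ACCEPT",
   "function": "record_measurement",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 5,
   "time": 1600432000
  },
  {
   "adversarial": false,
   "args": {
    "encrypted": false,
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S001\", \"value_hours\": 84.0, \"visit\": 2}",
    "subject_id": "OSLT-001-S001"
   },
   "expect": "ACCEPT",
   "function": "record_measurement",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 6,
   "time": 1600518400
  },
  {
   "adversarial": false,
   "args": {
    "encrypted": false,
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S002\", \"value_hours\": 162.7, \"visit\": 1}",
    "subject_id": "OSLT-001-S002"
   },
   "expect": "ACCEPT",
   "function": "record_measurement",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 6,
   "time": 1600518400
  },
  {
   "adversarial": false,
   "args": {
    "consent_hash": "6ba3147a5dc214377ca39562f68ff6f8b10624934a984bf8153297cb50700c28",
    "demographics": {
     "age_band": "38-",
     "arm": "treatment",
     "sex": "F"
    },
    "subject_id": "OSLT-001-S003"
   },
   "expect": "ACCEPT",
   "function": "add_subject",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 7,
   "time": 1600604800
  },
  {
   "adversarial": false,
   "args": {
    "encrypted": false,
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S002\", \"value_hours\": 86.0, \"visit\": 2}",
    "subject_id": "OSLT-001-S002"
   },
   "expect": "ACCEPT",
   "function": "record_measurement",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 7,
   "time": 1600604800
  },
  {
   "adversarial": false,
   "args": {
    "encrypted": false,
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S003\", \"value_hours\": 87.3, \"visit\": 1}",
    "subject_id": "OSLT-001-S003"
   },
   "expect": "ACCEPT",
   "function": "record_measurement",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 8,
   "time": 1600691200
  },
  {
   "adversarial": false,
   "args": {
    "encrypted": false,
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S003\", \"value_hours\": 46.2, \"visit\": 2}",
    "subject_id": "OSLT-001-S003"
   },
   "expect": "ACCEPT",
   "function": "record_measurement",
   "note": "",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 9,
   "time": 1600777600
  },
  {
   "adversarial": true,
   "args": {
    "consent_hash": "201ca629588e66aaa739d6f395237ddab71f4158f942933f3a28206d411a04d2",
    "demographics": {
     "age_band": "38-",
     "arm": "treatment",
     "sex": "F"
    },
    "subject_id": "OSLT-001-LATE-000"
   },
   "expect": "WINDOW_CLOSED",
   "function": "add_subject",
   "note": "late_enrolment",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 9,
   "time": 1600777600
  },
  {
   "adversarial": true,
   "args": {
    "encrypted": false,
    "payload": "{\"visit\": 99, \"value_hours\": 1.0}",
    "subject_id": "OSLT-001-S001"
   },
   "expect": "TRIAL_ENDED",
   "function": "record_measurement",
   "note": "post_end_measurement",
   "sender": "cro-1",
   "target_ref": "trial:OSLT-001",
   "tick": 12,
   "time": 1601036800
  }
 ],
 "header": {
  "measurement_distribution": {
   "family": "lognormal",
   "mu": 4.4998,
   "sigma": 0.35,
   "unit": "hours"
  },
  "n_events": 15,
  "seed": 2,
  "spec": {
   "adversarial_fraction": 0.25,
   "epoch": 1600000000,
   "n_measurements_per_subject": 2,
   "n_subjects_per_trial": 3,
   "n_trials": 1,
   "recruitment_window": [
    1600345600,
    1600691200
   ],
   "trial_end": 1600950400,
   "visit_interval": 86400
  },
  "trial_ids": [
   "OSLT-001"
  ]
 },
 "identities": [
  {
   "label": "regulator-1",
   "role": "regulator",
   "seed_hex": "fd458523524d6fc68ab9941c8a2f3623c6a4d7b51a8df5c7eceb02ddfdaefaad"
  },
  {
   "label": "cro-1",
   "role": "cro",
   "seed_hex": "210920e428eb42b5e9b3f7cc1a2f0a00d75c76f21403bf100e5f9948500ad85d"
  },
  {
   "label": "cro-rogue",
   "role": "cro",
   "seed_hex": "b136f89e8db51a735af5c13102174c2261e84097160e24bc294363705a374f0e"
  }
 ],
 "protocol_documents": {
  "OSLT-001": "SYNTHETIC TRIAL PROTOCOL OSLT-001\nA randomised synthetic influenza treatment trial (workload seed 2).\nPrimary endpoint: time_to_alleviation_of_symptoms \u2014 hours from first dose to alleviation of all influenza symptoms.\nSecondary endpoint: incidence_of_secondary_complications.\nRecruitment window: 1600345600..1600691200 (POSIX seconds, inclusive).\nTrial end: 1600950400.\nPlanned enrolment: 3 subjects, 2 visits each.\n"
 }
}
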