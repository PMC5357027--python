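{
 "encryption_keys": {
  "OSLT-001": "694854be8ff3dc5ecb35313e63e88a439eec5aab40e5ee8860bd3abe0c64773c"
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
    "encryption_pubkey": "90dd489b3d20906fd5b4848c5cc5d8db1333f7fc9b823561b48f52dfa3187083",
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
    "protocol_document_hash": "c39344e19e6e65fede440bf22396c6ef188e21319f44b6d5e056f31691638176",
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
    "document_hash": "c39344e19e6e65fede440bf22396c6ef188e21319f44b6d5e056f31691638176",
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
    "consent_hash": "166fb0767d734e4e7418a81199d6bf7556fcdc6adf90e95d9fede34a6bd9511f",
    "demographics": {
     "age_band": "28-",
     "arm": "placebo",
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
    "consent_hash": "301cad1d0d7f34e74ab99a4cfe371b489ccb107e14c83698e2d357340c6566d6",
    "demographics": {
     "age_band": "18-",
     "arm": "placebo",
     "sex": "M"
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
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S001\", \"value_hours\": 128.4, \"visit\": 1}",
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
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S001\", \"value_hours\": 80.0, \"visit\": 2}",
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
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S002\", \"value_hours\": 137.8, \"visit\": 1}",
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
    "consent_hash": "aa464439b83f3acb3dad8f02ec4a916df7e6ec4a8d309e5671c3d3f1917336bd",
    "demographics": {
     "age_band": "48-",
     "arm": "treatment",
     "sex": "M"
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
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S002\", \"value_hours\": 67.0, \"visit\": 2}",
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
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S003\", \"value_hours\": 83.6, \"visit\": 1}",
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
    "payload": "{\"endpoint\": \"time_to_alleviation_of_symptoms\", \"subject_id\": \"OSLT-001-S003\", \"value_hours\": 73.1, \"visit\": 2}",
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
    "consent_hash": "93dc51edfb006b780b8492ba1fc1b245a5996e0bab8e45f8e78dab25edb73d84",
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
  "seed": 1,
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
   "seed_hex": "23bef9cffb87be10144ab1c13f5b6743ef55997a329773392fb8f39dd1fb2406"
  },
  {
   "label": "cro-1",
   "role": "cro",
   "seed_hex": "68ddc618e0e7a40be784fd8644aca093900fc8ba31f79c14b97e402fdd6a1d32"
  },
  {
   "label": "cro-rogue",
   "role": "cro",
   "seed_hex": "68c921fe5f967a4dd0216ac12a358f272738f89fbb73177ec35b57b139543e04"
  }
 ],
 "protocol_documents": {
  "OSLT-001": "SYNTHETIC TRIAL PROTOCOL OSLT-001\nA randomised synthetic influenza treatment trial (workload seed 1).\nPrimary endpoint: time_to_alleviation_of_symptoms \u2014 hours from first dose to alleviation of all influenza symptoms.\nSecondary endpoint: incidence_of_secondary_complications.\nRecruitment window: 1600345600..1600691200 (POSIX seconds, inclusive).\nTrial end: 1600950400.\nPlanned enrolment: 3 subjects, 2 visits each.\n"
 }
}
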