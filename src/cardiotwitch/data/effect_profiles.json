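{
 "Ajmaline": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 2.0,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Astemizole": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": null,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Azimilide": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 1.07,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Bepridil": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.7,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Chlorpromazine": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 1.02,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Cisapride": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.015,
   "100": 0.015,
   "30": 0.02
  },
  "ce_prob_by_fold": {
   "100": 0.005
  },
  "hill_ic50_um": 0.02,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 2,
   "10": 4,
   "100": 5,
   "30": 5
  }
 },
 "Clarithromycin": {
  "ac_prob_by_fold": {
   "1": 0.0,
   "10": 0.02,
   "100": 0.06,
   "30": 0.04
  },
  "ce_prob_by_fold": {
   "100": 0.008,
   "30": 0.004
  },
  "hill_ic50_um": 16,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 2,
   "10": 10,
   "100": 30,
   "30": 20
  }
 },
 "Clozapine": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 1.5,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "D,L-Sotalol": {
  "ac_prob_by_fold": {
   "0.1": 0.0,
   "1": 0.005,
   "10": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": null,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "0.1": 0,
   "1": 5,
   "10": 15,
   "30": 30
  }
 },
 "Diltiazem": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 1.0,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Diphenhydramine": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.6,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Disopyramide": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 9.3,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Dofetilide": {
  "ac_prob_by_fold": {
   "1": 0.0,
   "10": 0.25,
   "100": 0.5,
   "30": 0.4
  },
  "ce_prob_by_fold": {
   "100": 0.006
  },
  "hill_ic50_um": null,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 2,
   "10": 17,
   "100": 26,
   "30": 21
  }
 },
 "Domperidone": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.02,
   "100": 0.06,
   "30": 0.04
  },
  "ce_prob_by_fold": {
   "10": 0.004,
   "100": 0.01,
   "30": 0.006
  },
  "hill_ic50_um": 0.2,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 4,
   "10": 10,
   "100": 26,
   "30": 18
  }
 },
 "Droperidol": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.18,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Erythromycin": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": null,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Flecainide": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 1.1,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Ibutilide": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 2.0,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Loratadine": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.0175,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Mexiletine": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {
   "30": 0.012
  },
  "hill_ic50_um": 0.9,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Mibefradil": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.18,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Moxifloxacin": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": null,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Nifedipine": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.04,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Nitrendipine": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.06,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Ondansetron": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 14,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Procainamide": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 2215,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Quinidine": {
  "ac_prob_by_fold": {
   "0.1": 0.0,
   "1": 0.01,
   "10": 0.03,
   "30": 0.05
  },
  "ce_prob_by_fold": {
   "30": 0.008
  },
  "hill_ic50_um": 3.6,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "0.1": 0,
   "1": 8,
   "10": 20,
   "30": 35
  }
 },
 "Ranolazine": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {
   "100": 0.02
  },
  "hill_ic50_um": 17,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 0,
   "10": 5,
   "100": 37,
   "30": 10
  }
 },
 "Sematilide": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": null,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Tamoxifen": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.99,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {}
 },
 "Terodiline": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.7,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Vandetanib": {
  "ac_prob_by_fold": {
   "1": 0.01,
   "10": 0.03,
   "3": 0.02,
   "30": 0.05
  },
  "ce_prob_by_fold": {},
  "hill_ic50_um": 2.7,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "1": 3,
   "10": 15,
   "3": 8,
   "30": 25
  }
 },
 "Verapamil": {
  "ac_prob_by_fold": {},
  "ce_prob_by_fold": {},
  "hill_ic50_um": 0.04,
  "hill_slope": 1.0,
  "tr90_pct_by_fold": {
   "0.2": 0,
   "2": 0,
   "22": 0,
   "222": 3
  }
 }
}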