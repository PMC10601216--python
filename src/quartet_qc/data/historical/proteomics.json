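{
  "metrics": {
    "cv_median": [
      0.03769571409333197,
      0.0825495959138571,
      0.08933509891663102,
      0.1228173393526738,
      0.14471544431416555,
      0.19153561253793236,
      0.19974765801519273,
      0.2269150210787341,
      0.26860410140101615,
      0.2797382323571687,
      0.3141316932850865,
      0.34315947086153853,
      0.35218335395896166,
      0.38536198170502567,
      0.40136907327567867,
      0.4260429245893426,
      0.4403131241100599,
      0.48778966337841556,
      0.4775180288226706,
      0.5167268026147324
    ],
    "missing_pct": [
      0.0,
      0.0022560631697687537,
      0.016779469825155106,
      0.00806924882629108,
      0.03211959739490823,
      0.05160197165742452,
      0.024707602339181286,
      0.031788472964943554,
      0.06819571865443425,
      0.0932061579651941,
      0.02821522309711286,
      0.06390494540783558,
      0.04938867438867439,
      0.050095419847328244,
      0.07131995133819952,
      0.10260311020960108,
      0.15691489361702127,
      0.011632825719120136,
      0.08159319412219644,
      0.15123456790123457
    ],
    "n_features": [
      600.0,
      591.0,
      591.0,
      568.0,
      563.0,
      541.0,
      570.0,
      561.0,
      545.0,
      498.0,
      508.0,
      519.0,
      518.0,
      524.0,
      548.0,
      493.0,
      564.0,
      394.0,
      431.0,
      594.0
    ],
    "rc": [
      0.9984845827520129,
      0.9920931449896917,
      0.9904070728122863,
      0.9828385299772835,
      0.9723564974441458,
      0.9507193104373146,
      0.9529467378607002,
      0.9379948723553931,
      0.9256491104695479,
      0.8988795233529381,
      0.8927670602891816,
      0.8606418386549713,
      0.8676548705561535,
      0.8340719899515652,
      0.8151746437107822,
      0.8163711532570149,
      0.7642697102829642,
      0.7754168419185037,
      0.722710248397884,
      0.7321501018562533
    ],
    "replicate_corr": [
      0.999117798107129,
      0.9955611078670162,
      0.994925693158362,
      0.9914384271296296,
      0.9857729538436203,
      0.9767380578210347,
      0.9747458736162224,
      0.965043031782281,
      0.9432807315220052,
      0.956996924063187,
      0.9417074727550361,
      0.9266370867934209,
      0.9156697283010796,
      0.8892285875929481,
      0.8982341315361673,
      0.8737987964064192,
      0.8700114436360785,
      0.8549135356679053,
      0.8298336368388864,
      0.8406122285808237
    ],
    "snr": [
      44.78392624464729,
      39.05352226490882,
      35.99731378310083,
      33.34207463066192,
      32.470124311353416,
      23.90422073276816,
      27.820945398448274,
      28.945522780466288,
      21.41713723656698,
      24.20435850200896,
      24.54336175921421,
      19.07070494534323,
      22.588556356902664,
      20.99611793146933,
      19.671142778662652,
      14.123246780188868,
      11.382304283574172,
      15.714526141693138,
      13.639833935404077,
      11.275304239390058
    ]
  },
  "omics": "proteomics",
  "scores": [
    1.0,
    0.9371141760093523,
    0.9002129665165949,
    0.8550143907413096,
    0.8025799085997929,
    0.6668244283543882,
    0.7428879130176633,
    0.7104555604402163,
    0.5635758330943783,
    0.515544425488451,
    0.5604065735544458,
    0.4532589967848869,
    0.4833284830631059,
    0.41131372328572785,
    0.3864991934320461,
    0.2486027663660071,
    0.08820215168054575,
    0.11314492980642785,
    0.06065496672023434,
    0.04439882655040306
  ],
  "version": "sim-2024.1"
}
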