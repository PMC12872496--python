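{
 "SR": {
  "state": [
   -78.87999963725379,
   0.004239633644213534,
   0.9424072464100111,
   0.9602687090986106,
   0.00018223811835549688,
   0.9926993674019806,
   0.963572520906384,
   0.0007013124043664713,
   0.9657105627072822,
   0.00020863341632864233,
   0.9647517377301507,
   0.0006065298033613285,
   0.0005780416327720288,
   0.00011238491932295687,
   0.9997262380368142,
   0.19352443090909305,
   0.007788702699582352,
   0.9993194783994774,
   0.20266699473004768,
   0.13225977255893878,
   0.14963942586405338,
   0.7880908787637745,
   0.7851551713061624,
   8.323004764145002,
   138.60054626636133,
   0.010423819874769246,
   13.612488682144301,
   0.00881211713784649,
   0.004159488726864391,
   0.01,
   2.2
  ],
  "bcl_ms": 1000.0,
  "n_beats": 440,
  "converged": true,
  "state_names": [
   "Vm",
   "m",
   "h",
   "j",
   "d",
   "f",
   "fCa",
   "a_to",
   "i_to",
   "a_ur",
   "i_ur",
   "pa",
   "xs",
   "RyR_o_ss",
   "RyR_c_ss",
   "RyR_a_ss",
   "RyR_o_bc",
   "RyR_c_bc",
   "RyR_a_bc",
   "Ca_ss",
   "Ca_bc",
   "Ca_SRss",
   "Ca_SRbc",
   "Na_i",
   "K_i",
   "CaMK_trap",
   "Ca_TnC",
   "RU_perm",
   "XB_attached",
   "XB_distortion",
   "SL"
  ]
 },
 "AF": {
  "state": [
   -82.63784124970365,
   0.0022871816494304744,
   0.9745196772075707,
   0.9840033095199961,
   0.00011393941542912927,
   0.9960333057418446,
   0.9873649566700982,
   0.0004984847718534109,
   0.9750133977367986,
   0.0001348297866226041,
   0.9594812944948042,
   0.0003315174526038079,
   0.0004816232438587909,
   5.636530850523405e-07,
   0.9999999871625596,
   0.14731854237129538,
   0.004621572172984903,
   0.9997761725596475,
   0.1377525333661308,
   0.07691435172551545,
   0.08287584491476606,
   0.5505122576162298,
   0.5507963623207619,
   7.624819087074489,
   139.4081907259139,
   0.4422165759621016,
   11.201752302283527,
   0.048319512605550896,
   0.022643328212337274,
   0.01,
   2.2
  ],
  "bcl_ms": 1000.0,
  "n_beats": 500,
  "converged": false,
  "state_names": [
   "Vm",
   "m",
   "h",
   "j",
   "d",
   "f",
   "fCa",
   "a_to",
   "i_to",
   "a_ur",
   "i_ur",
   "pa",
   "xs",
   "RyR_o_ss",
   "RyR_c_ss",
   "RyR_a_ss",
   "RyR_o_bc",
   "RyR_c_bc",
   "RyR_a_bc",
   "Ca_ss",
   "Ca_bc",
   "Ca_SRss",
   "Ca_SRbc",
   "Na_i",
   "K_i",
   "CaMK_trap",
   "Ca_TnC",
   "RU_perm",
   "XB_attached",
   "XB_distortion",
   "SL"
  ]
 },
 "AF_case1": {
  "state": [
   -82.6345036523374,
   0.0022884438922372804,
   0.9745022414993273,
   0.983994863995589,
   0.00011398669791050368,
   0.9961001925940636,
   0.9874375698335175,
   0.0004986328172999772,
   0.9750092503259216,
   0.00013487481030522951,
   0.9599047169524878,
   0.00032616413176811415,
   0.00047867549937139116,
   5.476325745393064e-07,
   0.9999999879056971,
   0.14738915292579993,
   0.004245300250240568,
   0.9997853014373183,
   0.1385818454027851,
   0.07670741758330035,
   0.08263592518877562,
   0.5516338221764803,
   0.5515739241671326,
   7.604398013279855,
   139.43266808387878,
   0.4387928285133647,
   8.214099311870523,
   0.0007109922155293656,
   0.00033746151029970684,
   0.01,
   2.2
  ],
  "bcl_ms": 1000.0,
  "n_beats": 500,
  "converged": false,
  "state_names": [
   "Vm",
   "m",
   "h",
   "j",
   "d",
   "f",
   "fCa",
   "a_to",
   "i_to",
   "a_ur",
   "i_ur",
   "pa",
   "xs",
   "RyR_o_ss",
   "RyR_c_ss",
   "RyR_a_ss",
   "RyR_o_bc",
   "RyR_c_bc",
   "RyR_a_bc",
   "Ca_ss",
   "Ca_bc",
   "Ca_SRss",
   "Ca_SRbc",
   "Na_i",
   "K_i",
   "CaMK_trap",
   "Ca_TnC",
   "RU_perm",
   "XB_attached",
   "XB_distortion",
   "SL"
  ]
 },
 "AF_case2": {
  "state": [
   -82.76778898460354,
   0.00223855922070888,
   0.9752386380788393,
   0.9844696413747607,
   0.0001121038879309059,
   0.9975725593140914,
   0.9887924359549409,
   0.0004926345541790569,
   0.9752864402744956,
   0.00013281034776344383,
   0.9765959568793046,
   0.0001981867884787369,
   0.00037720734124347316,
   7.969296926515304e-07,
   0.9999999309291056,
   0.13450457486844888,
   0.005684885698826377,
   0.9998249777457136,
   0.1249707627321974,
   0.07238233902161013,
   0.07615226832923977,
   0.48406919115003566,
   0.48472882349506924,
   7.6383408635582555,
   139.42968329942332,
   0.37629099809381905,
   10.445356103133596,
   0.03824047507337511,
   0.018028637416018758,
   0.01,
   2.2
  ],
  "bcl_ms": 1000.0,
  "n_beats": 500,
  "converged": false,
  "state_names": [
   "Vm",
   "m",
   "h",
   "j",
   "d",
   "f",
   "fCa",
   "a_to",
   "i_to",
   "a_ur",
   "i_ur",
   "pa",
   "xs",
   "RyR_o_ss",
   "RyR_c_ss",
   "RyR_a_ss",
   "RyR_o_bc",
   "RyR_c_bc",
   "RyR_a_bc",
   "Ca_ss",
   "Ca_bc",
   "Ca_SRss",
   "Ca_SRbc",
   "Na_i",
   "K_i",
   "CaMK_trap",
   "Ca_TnC",
   "RU_perm",
   "XB_attached",
   "XB_distortion",
   "SL"
  ]
 }
}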