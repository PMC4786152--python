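patient,art_sd
P00001,2011-05-25
P00002,2008-12-23
P00003,2009-07-20
P00004,2008-05-28
P00005,2009-01-18
P00006,2008-10-20
P00007,2008-04-11
P00008,2009-09-29
P00009,2008-08-04
P00010,2010-10-13
P00011,2009-03-06
P00012,2008-09-15
P00013,2009-10-20
P00014,2011-04-01
P00015,2008-12-15
P00016,2009-05-19
P00017,2010-01-08
P00018,2011-11-16
P00019,2011-12-08
P00020,2010-07-13
P00021,2009-09-05
P00022,2009-04-28
P00023,2008-08-31
P00024,2010-02-15
P00025,2010-12-14
P00026,2011-12-19
P00027,2008-06-22
P00028,2011-11-19
P00029,2010-11-24
P00030,2011-10-21
P00031,2008-11-24
P00032,2008-09-02
P00033,2008-12-31
P00034,2011-06-21
P00035,2008-02-06
P00036,2010-07-08
P00037,2010-09-25
P00038,2010-01-28
P00039,2008-08-01
P00040,2008-09-24
P00041,2010-06-21
P00042,2009-11-22
P00043,2009-02-06
P00044,2009-06-18
P00045,2008-06-18
P00046,2008-10-23
P00047,2011-04-05
P00048,2010-01-28
P00049,2008-08-15
P00050,2009-10-18
P00051,2008-03-22
P00052,2010-09-09
P00053,2008-12-23
P00054,2008-11-06
P00055,2010-08-01
P00056,2009-10-14
P00057,2008-10-29
P00058,2008-03-08
P00059,2011-12-31
P00060,2010-11-08
P00061,2008-04-21
P00062,2010-07-24
P00063,2009-02-27
P00064,2008-05-18
P00065,2011-08-01
P00066,2008-06-28
P00067,2011-06-21
P00068,2008-09-23
P00069,2010-12-27
P00070,2010-08-07
P00071,2008-11-23
P00072,2010-12-30
P00073,2008-08-13
P00074,2009-06-09
P00075,2011-02-23
P00076,2011-03-31
P00077,2009-10-20
P00078,2010-02-20
P00079,2010-02-14
P00080,2009-02-23
P00081,2008-09-03
P00082,2009-05-30
P00083,2009-04-09
P00084,2009-05-17
P00085,2011-01-10
P00086,2010-05-13
P00087,2008-11-01
P00088,2010-04-04
P00089,2008-04-09
P00090,2011-02-05
P00091,2010-12-12
P00092,2008-04-05
P00093,2008-10-02
P00094,2010-05-02
P00095,2011-09-16
P00096,2010-11-19
P00097,2010-04-17
P00098,2008-03-19
P00099,2009-04-27
P00100,2011-12-31
P00101,2009-07-16
P00102,2011-09-01
P00103,2008-09-02
P00104,2011-02-19
P00105,2009-03-15
P00106,2010-06-16
P00107,2011-03-17
P00108,2008-10-30
P00109,2008-07-19
P00110,2010-11-09
P00111,2010-08-05
P00112,2008-08-28
P00113,2010-02-11
P00114,2011-02-09
P00115,2011-12-18
P00116,2009-04-01
P00117,2010-04-20
P00118,2008-10-11
P00119,2010-07-26
P00120,2008-03-30
P00121,2008-10-07
P00122,2008-07-28
P00123,2010-12-10
P00124,2010-01-07
P00125,2010-08-11
P00126,2008-12-05
P00127,2010-12-19
P00128,2008-07-03
P00129,2010-03-12
P00130,2010-05-15
P00131,2008-10-16
P00132,2009-04-18
P00133,2010-05-14
P00134,2010-01-15
P00135,2008-08-01
P00136,2009-06-23
P00137,2010-04-02
P00138,2008-07-13
P00139,2010-06-27
P00140,2011-06-10
P00141,2010-07-09
P00142,2009-04-28
P00143,2009-06-08
P00144,2010-08-08
P00145,2011-08-31
P00146,2010-05-11
P00147,2009-10-11
P00148,2010-05-11
P00149,2011-03-11
P00150,2011-01-03
P00151,2008-12-10
P00152,2009-03-10
P00153,2012-01-13
P00154,2010-10-17
P00155,2008-04-16
P00156,2011-04-28
P00157,2008-04-20
P00158,2012-01-13
P00159,2009-12-08
P00160,2008-01-23
P00161,2011-12-31
P00162,2011-07-29
P00163,2008-04-05
P00164,2010-07-08
P00165,2011-08-28
P00166,2009-09-18
P00167,2011-01-09
P00168,2010-05-17
P00169,2008-04-05
P00170,2009-01-03
P00171,2010-12-13
P00172,2011-01-18
P00173,2011-09-08
P00174,2010-07-24
P00175,2011-10-24
P00176,2008-06-03
P00177,2012-01-20
P00178,2010-04-19
P00179,2009-08-10
P00180,2011-05-22
P00181,2010-02-19
P00182,2011-06-21
P00183,2010-10-25
P00184,2010-02-20
P00185,2010-02-14
P00186,2011-08-06
P00187,2011-10-30
P00188,2010-07-30
P00189,2011-12-17
P00190,2010-12-12
P00191,2009-07-17
P00192,2008-01-23
P00193,2008-09-24
P00194,2010-01-31
P00195,2009-08-14
P00196,2009-02-04
P00197,2008-10-28
P00198,2008-07-13
P00199,2008-11-08
P00200,2010-10-02
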