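patient,death_y,l_alive_d
P00001,0,2014-05-29
P00002,0,2011-12-28
P00003,0,2012-07-24
P00004,0,2011-06-02
P00005,1,2010-02-17
P00006,1,2009-12-17
P00007,0,2011-04-16
P00008,0,2012-07-19
P00009,0,2011-08-09
P00010,0,2013-08-18
P00011,0,2012-03-10
P00012,0,2011-09-20
P00013,0,2012-10-24
P00014,0,2012-11-15
P00015,0,2011-12-20
P00016,0,2009-08-05
P00017,0,2013-01-12
P00018,0,2014-11-20
P00019,0,2012-07-31
P00020,0,2013-07-17
P00021,0,2010-06-30
P00022,0,2010-04-24
P00023,0,2011-09-05
P00024,1,2012-02-12
P00025,0,2013-12-18
P00026,0,2014-12-23
P00027,0,2011-06-27
P00028,0,2014-11-23
P00029,0,2013-11-28
P00030,1,2012-04-20
P00031,0,2011-11-29
P00032,0,2011-09-07
P00033,1,2009-03-04
P00034,0,2014-06-25
P00035,0,2011-02-10
P00036,0,2013-05-13
P00037,0,2013-09-29
P00038,0,2013-02-01
P00039,0,2010-07-21
P00040,0,2011-09-29
P00041,0,2010-08-13
P00042,1,2012-10-01
P00043,0,2010-03-16
P00044,0,2012-06-22
P00045,0,2011-06-23
P00046,0,2011-10-28
P00047,0,2011-10-13
P00048,0,2013-02-01
P00049,0,2009-07-21
P00050,0,2012-10-22
P00051,0,2011-03-27
P00052,0,2011-01-18
P00053,0,2011-12-28
P00054,0,2011-11-11
P00055,0,2013-08-05
P00056,0,2012-10-18
P00057,0,2011-11-03
P00058,0,2011-03-13
P00059,0,2015-01-04
P00060,0,2013-11-12
P00061,0,2011-04-26
P00062,1,2013-06-22
P00063,0,2012-03-03
P00064,0,2011-05-23
P00065,0,2014-08-05
P00066,0,2011-07-03
P00067,0,2014-06-25
P00068,0,2011-09-28
P00069,0,2013-12-31
P00070,0,2013-08-11
P00071,0,2011-11-28
P00072,0,2011-03-09
P00073,0,2010-08-21
P00074,0,2009-12-12
P00075,0,2014-02-27
P00076,0,2014-04-04
P00077,0,2012-10-24
P00078,1,2012-02-08
P00079,0,2010-09-07
P00080,1,2010-05-02
P00081,0,2011-09-08
P00082,0,2012-06-03
P00083,1,2010-08-16
P00084,0,2010-02-20
P00085,0,2014-01-14
P00086,1,2011-07-04
P00087,0,2011-11-06
P00088,0,2012-02-24
P00089,0,2011-04-14
P00090,0,2014-02-09
P00091,0,2013-12-16
P00092,0,2011-04-10
P00093,0,2008-10-23
P00094,0,2013-05-06
P00095,0,2014-09-20
P00096,0,2013-08-18
P00097,0,2013-04-21
P00098,0,2010-04-11
P00099,0,2010-03-08
P00100,1,2013-07-01
P00101,0,2010-03-28
P00102,0,2014-09-05
P00103,0,2011-09-07
P00104,0,2014-02-23
P00105,0,2012-03-19
P00106,0,2013-06-20
P00107,0,2012-06-14
P00108,0,2011-11-04
P00109,0,2008-10-15
P00110,1,2012-11-03
P00111,0,2013-08-09
P00112,0,2011-09-02
P00113,0,2013-02-15
P00114,0,2014-02-13
P00115,0,2014-12-22
P00116,0,2012-04-05
P00117,0,2011-07-08
P00118,0,2011-10-16
P00119,1,2013-02-08
P00120,0,2011-04-04
P00121,0,2011-10-12
P00122,0,2011-08-02
P00123,0,2013-12-14
P00124,0,2013-01-11
P00125,0,2013-08-15
P00126,0,2011-12-10
P00127,0,2013-06-19
P00128,0,2011-07-08
P00129,0,2013-03-16
P00130,0,2013-05-19
P00131,0,2011-10-21
P00132,0,2012-04-22
P00133,0,2013-05-18
P00134,0,2013-01-19
P00135,0,2011-08-06
P00136,0,2012-06-27
P00137,0,2013-04-06
P00138,0,2011-07-18
P00139,0,2010-09-14
P00140,0,2014-06-14
P00141,1,2012-08-17
P00142,0,2012-05-02
P00143,0,2010-05-17
P00144,0,2013-08-12
P00145,0,2014-05-24
P00146,0,2013-05-15
P00147,0,2011-06-10
P00148,0,2013-05-15
P00149,0,2014-03-15
P00150,1,2011-01-03
P00151,0,2011-12-15
P00152,0,2012-03-14
P00153,0,2015-01-17
P00154,0,2013-10-21
P00155,0,2011-04-21
P00156,0,2013-02-14
P00157,1,2009-07-17
P00158,0,2013-04-10
P00159,0,2012-09-15
P00160,0,2011-01-27
P00161,1,2014-04-22
P00162,0,2014-08-02
P00163,0,2011-03-10
P00164,0,2010-10-13
P00165,0,2011-12-28
P00166,0,2011-05-06
P00167,0,2014-01-13
P00168,0,2013-05-21
P00169,0,2009-12-09
P00170,0,2012-01-08
P00171,0,2013-12-17
P00172,0,2014-01-22
P00173,0,2014-09-12
P00174,0,2013-07-28
P00175,0,2014-10-28
P00176,0,2011-06-08
P00177,0,2015-01-24
P00178,0,2013-04-23
P00179,0,2011-11-06
P00180,0,2014-05-26
P00181,0,2013-02-23
P00182,0,2014-06-25
P00183,0,2013-10-29
P00184,0,2013-02-24
P00185,0,2013-02-18
P00186,1,2012-03-21
P00187,1,2012-07-31
P00188,0,2013-05-23
P00189,1,2012-02-21
P00190,0,2013-12-16
P00191,0,2012-07-21
P00192,0,2011-01-27
P00193,0,2009-08-03
P00194,0,2013-02-04
P00195,0,2012-08-18
P00196,0,2012-02-09
P00197,0,2011-11-02
P00198,0,2011-07-18
P00199,0,2009-05-11
P00200,0,2012-06-04
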