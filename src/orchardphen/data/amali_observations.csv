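year,event,predicted,observed
2010,G1 adults,2010-04-28,2010-04-24
2011,G1 adults,2011-04-11,2011-04-04
2012,G1 adults,2012-04-30,2012-05-05
2013,G1 adults,2013-05-04,2013-05-07
2014,G1 adults,2014-04-05,2014-04-12
2015,G1 adults,2015-04-26,2015-05-05
2016,G1 adults,2016-05-04,2016-05-01
2017,G1 adults,2017-04-11,2017-04-08
2018,G1 adults,2018-04-19,2018-04-20
2019,G1 adults,2019-04-18,2019-04-16
2020,G1 adults,2020-04-10,2020-04-11
2010,G2 adults,2010-06-11,NA
2011,G2 adults,2011-05-20,NA
2012,G2 adults,2012-06-06,2012-06-15
2013,G2 adults,2013-06-18,2013-06-10
2014,G2 adults,2014-05-25,2014-05-23
2015,G2 adults,2015-06-10,2015-06-04
2016,G2 adults,2016-06-06,2016-06-06
2017,G2 adults,2017-05-27,2017-05-25
2018,G2 adults,2018-05-24,2018-05-26
2019,G2 adults,2019-06-02,2019-05-27
2020,G2 adults,2020-05-20,2020-05-23
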